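"""Rate summaries and per-protein history tracking."""

import pytest

from domrearr import (
    ConsistencyError,
    infer_all,
    summarize_rates,
    track_proteins,
)
from domrearr.events import EventType, RearrangementEvent, Solution
from domrearr.rates import SOLUTION_TYPES

from conftest import arr
from test_events import build_reconstructions


def ev(etype, edge, sources, result):
    return RearrangementEvent(
        etype,
        edge,
        tuple(arr(s) for s in sources),
        arr(result) if result else None,
    )


class TestSummarizeRates:
    def test_event_percentages(self, quartet):
        events = [
            ev(EventType.FUSION, ("N1", "A"), ["X", "Y"], "X Y"),
            ev(EventType.FUSION, ("N1", "B"), ["X", "Z"], "X Z"),
            ev(EventType.FISSION, ("N2", "C"), ["X Y"], "X"),
            ev(EventType.SINGLE_LOSS, ("N2", "D"), ["Z"], None),
        ]
        summary = summarize_rates([], events, quartet)
        pct = summary.percentages()
        assert pct[EventType.FUSION] == pytest.approx(50.0)
        assert pct[EventType.FISSION] == pytest.approx(25.0)
        assert pct[EventType.SINGLE_LOSS] == pytest.approx(25.0)
        assert pct[EventType.TERMINAL_GAIN] == 0.0
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_all_zero(self, quartet):
        summary = summarize_rates([], [], quartet)
        assert summary.event_total == 0
        assert all(v == 0.0 for v in summary.percentages().values())

    def test_solution_partition_percentages(self, quartet):
        sols = [
            Solution("s1", arr("X Y"), ("N1", "A"), "exact"),
            Solution("s2", arr("X Z"), ("N1", "B"), "complex"),
        ]
        summary = summarize_rates(sols, [], quartet)
        spct = summary.solution_percentages()
        assert spct["exact"] == pytest.approx(50.0)
        assert spct["complex"] == pytest.approx(50.0)

    def test_invariant_under_permutation_and_per_node_sums(self, quartet):
        events = [
            ev(EventType.FUSION, ("N1", "A"), ["X", "Y"], "X Y"),
            ev(EventType.FISSION, ("N2", "C"), ["X Y"], "X"),
            ev(EventType.SINGLE_LOSS, ("N2", "D"), ["Z"], None),
        ]
        a = summarize_rates([], events, quartet)
        b = summarize_rates([], list(reversed(events)), quartet)
        assert a.totals == b.totals
        per_node_sum = {}
        for row in a.per_node.values():
            for t, c in row["events"].items():
                per_node_sum[t] = per_node_sum.get(t, 0) + c
        assert per_node_sum == dict(a.totals)

    def test_tsv_rendering(self, quartet, tmp_path):
        events = [ev(EventType.FUSION, ("N1", "A"), ["X", "Y"], "X Y")]
        summary = summarize_rates([], events, quartet)
        path = tmp_path / "rates.tsv"
        summary.write_totals_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[1] == "event\tfusion\t1\t100.00"
        assert len(lines) == 1 + 6 + len(SOLUTION_TYPES)


def tlr_like_fixture(quartet):
    """d emerges at the root; fused with the ancestral (L M) protein at N1;
    a novel domain E accretes at the leaf edge into A."""
    base = {arr("d"), arr("L M")}
    leaf_arrs = {
        "A": base | {arr("d L M"), arr("d L M E")},
        "B": base | {arr("d L M")},
        "C": set(base),
        "D": set(base),
    }
    dollo, fitch = build_reconstructions(quartet, leaf_arrs)
    solutions, events = infer_all(quartet, dollo, fitch)
    architectures = {}
    for leaf, arrs in leaf_arrs.items():
        architectures[leaf] = {}
        for i, a in enumerate(sorted(arrs)):
            pid = f"{leaf}_p{i}"
            from domrearr import ProteinArchitecture

            architectures[leaf][pid] = ProteinArchitecture(pid, leaf, a)
    return solutions, events, architectures


class TestTrackProteins:
    def test_single_fusion_step(self, quartet):
        base = {arr("X"), arr("Y")}
        leaf_arrs = {
            "A": base | {arr("X Y")},
            "B": base | {arr("X Y")},
            "C": set(base),
            "D": set(base),
        }
        dollo, fitch = build_reconstructions(quartet, leaf_arrs)
        solutions, events = infer_all(quartet, dollo, fitch)
        from domrearr import ProteinArchitecture

        architectures = {"A": {"p1": ProteinArchitecture("p1", "A", arr("X Y"))}}
        (hist,) = track_proteins(["p1"], quartet, solutions, architectures, events)
        sol_steps = [s for s in hist.steps if s.solution is not None]
        assert len(sol_steps) == 1
        assert sol_steps[0].node == "N1"
        assert sol_steps[0].solution.chain[0].type is EventType.FUSION

    def test_ancestral_arrangement_flagged(self, quartet):
        base = {arr("X Y")}
        leaf_arrs = {l: set(base) for l in "ABCD"}
        dollo, fitch = build_reconstructions(quartet, leaf_arrs)
        solutions, events = infer_all(quartet, dollo, fitch)
        from domrearr import ProteinArchitecture

        architectures = {"A": {"p1": ProteinArchitecture("p1", "A", arr("X Y"))}}
        (hist,) = track_proteins(["p1"], quartet, solutions, architectures, events)
        assert hist.ancestral and hist.steps == []

    def test_tlr_like_three_steps_in_root_to_leaf_order(self, quartet):
        solutions, events, architectures = tlr_like_fixture(quartet)
        pid = next(
            p
            for p, a in architectures["A"].items()
            if a.arrangement == arr("d L M E")
        )
        (hist,) = track_proteins([pid], quartet, solutions, architectures, events)
        assert [s.node for s in hist.steps] == ["N3", "N1", "A"]
        kinds = [
            s.solution.chain[0].type if s.solution else s.event.type
            for s in hist.steps
        ]
        assert kinds == [
            EventType.SINGLE_EMERGENCE,
            EventType.FUSION,
            EventType.TERMINAL_GAIN,
        ]
        assert not hist.has_gaps

    def test_unknown_protein_listed(self, quartet):
        solutions, events, architectures = tlr_like_fixture(quartet)
        with pytest.raises(ConsistencyError, match="nope1.*nope2"):
            track_proteins(
                ["nope1", "nope2"], quartet, solutions, architectures, events
            )

    def test_referential_integrity(self, quartet):
        solutions, events, architectures = tlr_like_fixture(quartet)
        ids = [p for leaf in architectures.values() for p in leaf]
        histories = track_proteins(ids, quartet, solutions, architectures, events)
        pool = {id(s) for s in solutions}
        for hist in histories:
            for step in hist.steps:
                if step.solution is not None:
                    assert id(step.solution) in pool
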