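"""Rate summaries and per-protein evolutionary histories.

`summarize_rates` aggregates inferred events and solutions into the usual
per-clade table shape: counts per event type (fusion, fission, terminal
loss, terminal gain, single loss, single gain) with percentages of the event
total, the analogous solution-type partition, and per-node breakdowns.

`track_proteins` follows user-specified proteins root→leaf along the species
path and reports every solution on that path that contributed to the
protein's extant arrangement — directly, or indirectly as a source somewhere
inside the chain of a later step.  A tracked lineage may be incomplete when
one of its gains was classified complex; such histories are flagged rather
than dropped.  All carriers of the same arrangement in the same species
share identical history steps: the method is arrangement-based, not
gene-tree based, and performs no paralog resolution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .arrangements import DomainArrangement, ProteinArchitecture
from .errors import ConsistencyError
from .events import (
    EVENT_TYPE_ORDER,
    EventType,
    RearrangementEvent,
    Solution,
)
from .tree import SpeciesTree

__all__ = [
    "RatesSummary",
    "TrackStep",
    "ProteinHistory",
    "SOLUTION_TYPES",
    "summarize_rates",
    "track_proteins",
]

SOLUTION_TYPES = ("exact", "inferred", "multi_step", "complex")


@dataclass
class RatesSummary:
    per_node: dict[str, dict[str, Counter]] = field(default_factory=dict)
    totals: Counter = field(default_factory=Counter)
    solution_totals: Counter = field(default_factory=Counter)

    @property
    def event_total(self) -> int:
        return sum(self.totals.values())

    @property
    def solution_total(self) -> int:
        return sum(self.solution_totals.values())

    def percentages(self) -> dict[EventType, float]:
        total = self.event_total
        return {
            t: (100.0 * self.totals[t] / total if total else 0.0)
            for t in EVENT_TYPE_ORDER
        }

    def solution_percentages(self) -> dict[str, float]:
        total = self.solution_total
        return {
            s: (100.0 * self.solution_totals[s] / total if total else 0.0)
            for s in SOLUTION_TYPES
        }

    def write_totals_tsv(self, path) -> None:
        """Totals in the conventional table style: ``count (percent%)``."""
        pct = self.percentages()
        spct = self.solution_percentages()
        with open(path, "w") as fh:
            fh.write("category\tname\tcount\tpercent\n")
            for t in EVENT_TYPE_ORDER:
                fh.write(f"event\t{t.value}\t{self.totals[t]}\t{pct[t]:.2f}\n")
            for s in SOLUTION_TYPES:
                fh.write(f"solution\t{s}\t{self.solution_totals[s]}\t{spct[s]:.2f}\n")

    def write_per_node_tsv(self, path, tree: SpeciesTree) -> None:
        with open(path, "w") as fh:
            header = ["node"] + [t.value for t in EVENT_TYPE_ORDER] + list(SOLUTION_TYPES)
            fh.write("\t".join(header) + "\n")
            for node in tree.postorder():
                row = self.per_node.get(node.id)
                if row is None:
                    continue
                cells = [node.id]
                cells += [str(row["events"][t]) for t in EVENT_TYPE_ORDER]
                cells += [str(row["solutions"][s]) for s in SOLUTION_TYPES]
                fh.write("\t".join(cells) + "\n")


def summarize_rates(
    solutions: Iterable[Solution],
    events: Iterable[RearrangementEvent],
    tree: SpeciesTree,
) -> RatesSummary:
    """Aggregate events and solutions into totals and per-node counts."""
    summary = RatesSummary()

    def node_row(node_id: str) -> dict[str, Counter]:
        return summary.per_node.setdefault(
            node_id, {"events": Counter(), "solutions": Counter()}
        )

    for event in events:
        summary.totals[event.type] += 1
        node_row(event.edge[1])["events"][event.type] += 1
    for sol in solutions:
        summary.solution_totals[sol.solution_type] += 1
        node_row(sol.edge[1])["solutions"][sol.solution_type] += 1
    return summary


@dataclass
class TrackStep:
    """One change on a tracked protein's lineage.

    Either a solution explaining a gain on the path, or a bare single-domain
    emergence event (a domain origin has no gain solution when the bare
    arrangement was never itself gained on an edge, e.g. at the root).
    """

    node: str
    solution: Optional[Solution] = None
    event: Optional[RearrangementEvent] = None

    @property
    def target_key(self) -> str:
        if self.solution is not None:
            return self.solution.target.key
        assert self.event is not None and self.event.result is not None
        return self.event.result.key


@dataclass
class ProteinHistory:
    protein_id: str
    leaf: str
    path: list[str]
    steps: list[TrackStep]
    ancestral: bool = False
    has_gaps: bool = False


def track_proteins(
    protein_ids: Iterable[str],
    tree: SpeciesTree,
    solutions: Iterable[Solution],
    architectures: dict[str, dict[str, ProteinArchitecture]],
    events: Iterable[RearrangementEvent] = (),
) -> list[ProteinHistory]:
    """Trace the root→leaf event history of each given protein."""
    ids = list(protein_ids)
    where: dict[str, tuple[str, ProteinArchitecture]] = {}
    for species in sorted(architectures):
        for pid, arch in architectures[species].items():
            where.setdefault(pid, (species, arch))
    unknown = sorted(set(ids) - set(where))
    if unknown:
        raise ConsistencyError(
            "unknown protein id(s): " + ", ".join(unknown)
        )

    sol_index: dict[tuple[str, DomainArrangement], Solution] = {}
    for sol in solutions:
        sol_index[(sol.edge[1], sol.target)] = sol
    emergence_index: dict[tuple[str, DomainArrangement], RearrangementEvent] = {}
    for event in events:
        if event.type is EventType.SINGLE_EMERGENCE and event.result is not None:
            emergence_index[(event.edge[1], event.result)] = event

    histories: list[ProteinHistory] = []
    for pid in ids:
        species, arch = where[pid]
        path_nodes = [n.id for n in tree.path_to(species)]
        target = arch.arrangement

        # arrangements feeding the extant one through chains on this path
        relevant: set[DomainArrangement] = {target}
        changed = True
        while changed:
            changed = False
            for node_id in path_nodes:
                for arr in list(relevant):
                    sol = sol_index.get((node_id, arr))
                    if sol is None:
                        continue
                    for ev in sol.chain:
                        for src in ev.sources:
                            if src not in relevant:
                                relevant.add(src)
                                changed = True

        steps: list[TrackStep] = []
        has_gaps = False
        for node_id in path_nodes:
            for arr in sorted(relevant):
                sol = sol_index.get((node_id, arr))
                if sol is not None:
                    steps.append(TrackStep(node_id, solution=sol))
                    if sol.solution_type == "complex":
                        has_gaps = True
                else:
                    ev = emergence_index.get((node_id, arr))
                    if ev is not None:
                        steps.append(TrackStep(node_id, event=ev))
        histories.append(
            ProteinHistory(
                protein_id=pid,
                leaf=species,
                path=path_nodes,
                steps=steps,
                ancestral=not steps,
                has_gaps=has_gaps,
            )
        )
    return histories
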