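"""Alignment scoring and sequence-based candidate resolution."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from domrearr import (
    DomRearrError,
    ScoringScheme,
    pairwise_align,
    resolve,
    score_candidate,
)
from domrearr.events import EventType, RearrangementEvent

from conftest import arr, diverge, make_provider, random_seq
from oracles import gotoh_score

# Hand-computed affine-gap global scores (gap open -10, extend -1) from the
# published BLOSUM62 entries: A/A=4 W/W=11 C/C=9 D/D=6 E/E=5 F/F=6 G/G=6
# P/P=7 R/R=5 K/K=5 A/W=-3 Q/R=1.
HAND_CASES = [
    ("A", "A", 4, 1),
    ("W", "W", 11, 1),
    ("AAAA", "AAAA", 16, 4),
    ("AC", "AC", 13, 2),
    ("ACDE", "ACDE", 24, 4),
    ("ACDEFG", "ACDEFG", 36, 6),
    ("A", "W", -3, 1),
    ("AW", "A", 4 - 10, 2),
    ("AAAA", "AA", 8 - 11, 4),
    ("AAAAAA", "AA", 8 - 13, 6),
    ("PQR", "PR", 7 + 5 - 10, 3),
    ("KKKK", "KK", 10 - 11, 4),
]


class TestPairwiseAlign:
    @pytest.mark.parametrize("a,b,score,length", HAND_CASES)
    def test_hand_computed_scores(self, a, b, score, length):
        got_score, got_length = pairwise_align(a, b)
        assert got_score == score
        assert got_length == length

    def test_agrees_with_independent_gotoh(self):
        matrix = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(7)
        for _ in range(150):
            a = random_seq(rng, int(rng.integers(1, 61)))
            b = random_seq(rng, int(rng.integers(1, 61)))
            score, _ = pairwise_align(a, b)
            assert score == pytest.approx(gotoh_score(a, b, matrix))

    def test_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            a, b = random_seq(rng, 25), random_seq(rng, 40)
            assert pairwise_align(a, b)[0] == pairwise_align(b, a)[0]

    def test_self_score_maximal_among_equal_length(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            a = random_seq(rng, 30)
            b = random_seq(rng, 30)
            assert pairwise_align(a, a)[0] >= pairwise_align(a, b)[0]

    def test_illegal_residue_and_empty_rejected(self):
        with pytest.raises(DomRearrError):
            pairwise_align("MK1", "MK")
        with pytest.raises(DomRearrError):
            pairwise_align("", "MK")

    def test_custom_matrix_file(self, tmp_path):
        matrix = substitution_matrices.load("BLOSUM45")
        path = tmp_path / "blosum45.mat"
        path.write_text(str(matrix))
        scheme = ScoringScheme.from_file(path)
        score, _ = pairwise_align("W", "W", scheme)
        assert score == matrix["W", "W"]

    def test_bad_gap_penalties_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=-1, gap_extend=-10)


EDGE = ("N3", "N1")


def planted_fixture(rng, decoy_divergence=0.4):
    """Quartet fixture: AB gained at N1; fusion sources identical to the
    target's domains, the ABC decoy's A/B subsequences diverged."""
    sA, sB, sC = random_seq(rng), random_seq(rng), random_seq(rng)
    from domrearr import SpeciesTree

    tree = SpeciesTree.from_newick("((A,B),(C,D));")
    provider = make_provider(
        tree,
        {
            "A": {"pAB": ("X Y", [sA, sB])},
            "B": {"pX": ("X", [sA]), "pY": ("Y", [sB])},
            "C": {
                "pXYZ": (
                    "X Y Z",
                    [
                        diverge(rng, sA, decoy_divergence),
                        diverge(rng, sB, decoy_divergence),
                        sC,
                    ],
                )
            },
            "D": {"pX": ("X", [sA]), "pY": ("Y", [sB]), "pXYZ": ("X Y Z", [sA, sB, sC])},
        },
    )
    fusion = RearrangementEvent(
        EventType.FUSION, EDGE, (arr("X"), arr("Y")), arr("X Y")
    )
    decoy = RearrangementEvent(
        EventType.TERMINAL_LOSS, EDGE, (arr("X Y Z"),), arr("X Y")
    )
    return provider, fusion, decoy


class TestRepresentativeSequences:
    def test_nearest_exemplar_and_tie_rule(self, quartet):
        provider = make_provider(
            quartet,
            {
                "A": {"p2": ("X Y", ["AAAA", "CCCC"])},
                "C": {"p1": ("X Y", ["WWWW", "DDDD"])},
            },
        )
        # N1 is 1 edge from A, 3 edges from C
        assert provider.representative_sequences(arr("X Y"), "N1") == ["AAAA", "CCCC"]
        # at the root both are 2 edges away: smaller protein id wins
        assert provider.representative_sequences(arr("X Y"), "N3") == ["WWWW", "DDDD"]

    def test_missing_exemplar_returns_none(self, quartet):
        provider = make_provider(quartet, {"A": {"p1": ("X", ["AAAA"])}})
        assert provider.representative_sequences(arr("Z"), "N1") is None


class TestScoreCandidate:
    def test_identical_fusion_beats_diverged_truncation(self):
        rng = np.random.default_rng(17)
        provider, fusion, decoy = planted_fixture(rng)
        s_fusion = score_candidate(fusion, arr("X Y"), provider)
        s_decoy = score_candidate(decoy, arr("X Y"), provider)
        assert s_fusion is not None and s_decoy is not None
        assert s_fusion.normalized > s_decoy.normalized
        assert s_fusion.aligned_length == 120

    def test_missing_exemplar_scores_none(self, quartet):
        provider = make_provider(quartet, {"A": {"p1": ("X Y", ["AAAA", "CCCC"])}})
        fusion = RearrangementEvent(
            EventType.FUSION, EDGE, (arr("X"), arr("Y")), arr("X Y")
        )
        assert score_candidate(fusion, arr("X Y"), provider) is None


class TestResolve:
    def test_single_candidate_is_unique(self):
        rng = np.random.default_rng(19)
        provider, fusion, _ = planted_fixture(rng)
        chosen, scores, how = resolve([fusion], arr("X Y"), provider)
        assert (chosen, scores, how) == (fusion, {}, "unique")

    def test_distinct_scores_resolved_by_sequence(self):
        rng = np.random.default_rng(23)
        provider, fusion, decoy = planted_fixture(rng)
        chosen, scores, how = resolve([decoy, fusion], arr("X Y"), provider)
        assert chosen == fusion
        assert how == "sequence"
        assert len(scores) == 2

    def test_unscorable_falls_back_to_priority(self, quartet):
        provider = make_provider(quartet, {"A": {"p1": ("X Y", ["AAAA", "CCCC"])}})
        fusion = RearrangementEvent(
            EventType.FUSION, EDGE, (arr("X"), arr("Y")), arr("X Y")
        )
        decoy = RearrangementEvent(
            EventType.TERMINAL_LOSS, EDGE, (arr("X Y Z"),), arr("X Y")
        )
        chosen, _, how = resolve([decoy, fusion], arr("X Y"), provider)
        assert chosen == fusion and how == "priority"

    def test_deterministic_across_runs(self):
        rng1, rng2 = np.random.default_rng(29), np.random.default_rng(29)
        p1, f1, d1 = planted_fixture(rng1)
        p2, f2, d2 = planted_fixture(rng2)
        assert resolve([f1, d1], arr("X Y"), p1) == resolve([f2, d2], arr("X Y"), p2)

    def test_planted_true_candidate_always_wins(self):
        """Exact-match candidate vs >=30% diverged decoy: 50 random fixtures."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            provider, fusion, decoy = planted_fixture(
                rng, decoy_divergence=0.3 + 0.4 * rng.random()
            )
            chosen, _, how = resolve([decoy, fusion], arr("X Y"), provider)
            assert chosen == fusion and how == "sequence"
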