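"""Sequence-based resolution of ambiguous rearrangement candidates.

When several single-step events could explain the same gained arrangement,
the candidates are scored by optimal global pairwise alignment (affine gap
penalties, BLOSUM62 by default) between the domain subsequences of the
candidate's source arrangement and those of the gained arrangement.  The
true precursor's domains are expected to be more similar to the child's
domains than a decoy's, so the candidate with the highest
score-per-aligned-column wins.  Normalising by aligned columns makes a
fusion (two source alignments) comparable with a truncation (one longer
source alignment).

Ancestral nodes carry no sequences, so each arrangement is represented by an
*exemplar*: the extant carrier protein at the leaf closest to the node in
edge count (ties broken by smallest protein id), sliced into per-position
domain subsequences by its annotation envelopes.  When no exemplar exists
the candidate is unscorable and resolution falls back to a fixed
type-priority order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio.Align import PairwiseAligner, substitution_matrices

from .arrangements import DomainArrangement, ProteinArchitecture
from .errors import DomRearrError
from .events import EventType, RearrangementEvent, _priority_resolve
from .tree import SpeciesTree

__all__ = [
    "ScoringScheme",
    "CandidateScore",
    "pairwise_align",
    "SequenceProvider",
    "SequenceResolver",
    "resolve",
    "score_candidate",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` is charged for the first residue of a gap and ``gap_extend``
    for each further residue, in matrix (half-bit) units.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = -10
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    @classmethod
    def from_file(cls, path, gap_open: int = -10, gap_extend: int = -1) -> "ScoringScheme":
        """Load an NCBI-format substitution matrix from *path*."""
        with open(path) as fh:
            matrix = substitution_matrices.read(fh)
        name = str(path)
        _FILE_MATRICES[name] = matrix
        return cls(matrix_name=name, gap_open=gap_open, gap_extend=gap_extend)


_FILE_MATRICES: dict[str, object] = {}


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    if name in _FILE_MATRICES:
        return _FILE_MATRICES[name]
    return substitution_matrices.load(name)


@lru_cache(maxsize=None)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass(frozen=True)
class CandidateScore:
    candidate: RearrangementEvent
    raw_score: float
    aligned_length: int
    normalized: float


def pairwise_align(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> tuple[float, int]:
    """Optimal global alignment score and column count of two sequences."""
    if not a or not b:
        raise DomRearrError("pairwise_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    alphabet = set(str(scheme.matrix.alphabet))
    for seq in (a, b):
        bad = set(seq) - alphabet
        if bad:
            raise DomRearrError(
                f"illegal residue(s) {sorted(bad)} in sequence {seq[:20]!r}..."
            )
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend)
    alignment = next(iter(aligner.align(a, b)))
    return alignment.score, alignment.length


class SequenceProvider:
    """Maps (arrangement, node) to exemplar per-position domain subsequences."""

    def __init__(
        self,
        tree: SpeciesTree,
        architectures: dict[str, dict[str, ProteinArchitecture]],
        sequences: dict[str, dict[str, str]],
    ) -> None:
        self.tree = tree
        self.architectures = architectures
        self.sequences = sequences
        self._carriers: dict[DomainArrangement, list[tuple[str, str]]] = {}
        for species in sorted(architectures):
            for pid in sorted(architectures[species]):
                arch = architectures[species][pid]
                if sequences.get(species, {}).get(pid):
                    self._carriers.setdefault(arch.arrangement, []).append((species, pid))
        self._cache: dict[tuple[DomainArrangement, str], Optional[list[str]]] = {}

    def representative_sequences(
        self, arrangement: DomainArrangement, node_id: str
    ) -> Optional[list[str]]:
        """Domain subsequences of the nearest extant carrier, or ``None``."""
        key = (arrangement, node_id)
        if key in self._cache:
            return self._cache[key]
        carriers = self._carriers.get(arrangement)
        result: Optional[list[str]] = None
        if carriers:
            node = self.tree.node(node_id)
            best = min(
                carriers,
                key=lambda sp: (
                    self.tree.edge_distance(self.tree.node(sp[0]), node),
                    sp[1],
                ),
            )
            species, pid = best
            arch = self.architectures[species][pid]
            seq = self.sequences[species][pid]
            slices = [seq[start - 1 : end] for start, end in arch.position_spans]
            if all(slices) and len(slices) == len(arrangement):
                result = slices
        self._cache[key] = result
        return result


def _position_map(
    candidate: RearrangementEvent, target: DomainArrangement
) -> Optional[list[tuple[int, int, int]]]:
    """(source index, source position, target position) triples, or None."""
    td = target.domains
    if candidate.type is EventType.FUSION:
        x, y = candidate.sources
        return [(0, i, i) for i in range(len(x))] + [
            (1, j, len(x) + j) for j in range(len(y))
        ]
    if candidate.type in (EventType.FISSION, EventType.TERMINAL_LOSS):
        (p,) = candidate.sources
        pd = p.domains
        if pd[: len(td)] == td:
            return [(0, i, i) for i in range(len(td))]
        if pd[len(pd) - len(td):] == td:
            off = len(pd) - len(td)
            return [(0, off + i, i) for i in range(len(td))]
        return None
    if candidate.type is EventType.TERMINAL_GAIN:
        (p,) = candidate.sources
        pd = p.domains
        if td[: len(pd)] == pd:
            return [(0, i, i) for i in range(len(pd))]
        if td[1:] == pd:
            return [(0, i, i + 1) for i in range(len(pd))]
        return None
    return None


def score_candidate(
    candidate: RearrangementEvent,
    target: DomainArrangement,
    seq_provider: SequenceProvider,
    scheme: Optional[ScoringScheme] = None,
) -> Optional[CandidateScore]:
    """Alignment score of a candidate's sources against the gained arrangement.

    Every source domain position is aligned against the target position it
    maps onto; the normalised score is the summed alignment score divided by
    the summed column count.  Returns ``None`` when any exemplar is missing.
    """
    scheme = scheme or ScoringScheme()
    mapping = _position_map(candidate, target)
    if mapping is None:
        return None
    parent, child = candidate.edge
    target_seqs = seq_provider.representative_sequences(target, child)
    if target_seqs is None:
        return None
    source_seqs: list[Optional[list[str]]] = []
    for source in candidate.sources:
        at = parent if parent is not None else child
        source_seqs.append(seq_provider.representative_sequences(source, at))
    if any(s is None for s in source_seqs):
        return None
    raw = 0.0
    columns = 0
    for si, sp, tp in mapping:
        score, length = pairwise_align(source_seqs[si][sp], target_seqs[tp], scheme)
        raw += score
        columns += length
    if columns == 0:
        return None
    return CandidateScore(candidate, raw, columns, raw / columns)


def resolve(
    candidates: list[RearrangementEvent],
    target: DomainArrangement,
    seq_provider: Optional[SequenceProvider],
    scheme: Optional[ScoringScheme] = None,
) -> tuple[RearrangementEvent, dict[tuple, float], str]:
    """Pick one candidate: unique, by sequence similarity, or by priority.

    A single candidate is returned as-is.  Otherwise all candidates are
    scored; a strict maximum of the normalised score decides.  Ties or any
    unscorable candidate fall back to the fixed type-priority order
    (fusion > fission > terminal loss > terminal gain), then canonical key.
    """
    if not candidates:
        raise ValueError("resolve requires at least one candidate")
    if len(candidates) == 1:
        return candidates[0], {}, "unique"
    scores: dict[tuple, float] = {}
    all_scored = seq_provider is not None
    if seq_provider is not None:
        for cand in candidates:
            cs = score_candidate(cand, target, seq_provider, scheme)
            if cs is None:
                all_scored = False
            else:
                scores[cand.key()] = cs.normalized
    if all_scored:
        top = max(scores.values())
        leaders = [c for c in candidates if scores[c.key()] == top]
        if len(leaders) == 1:
            return leaders[0], scores, "sequence"
    return _priority_resolve(candidates), scores, "priority"


class SequenceResolver:
    """Bundles a provider and scheme behind the interface `infer_all` expects."""

    def __init__(self, provider: SequenceProvider, scheme: Optional[ScoringScheme] = None):
        self.provider = provider
        self.scheme = scheme or ScoringScheme()

    def resolve(self, candidates, target):
        return resolve(candidates, target, self.provider, self.scheme)

    def score_event(self, event, target):
        return score_candidate(event, target, self.provider, self.scheme)
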