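"""Canonical domain arrangements and per-species content sets.

A *domain arrangement* is the N→C ordered tuple of Pfam family accessions of
one protein.  Arrangements compare and hash by their canonical key (accessions
joined by single spaces), which is also the serialisation used in every output
table.  Consecutive repeats of the same family may optionally be collapsed to
a single position — tandem repeat expansion/contraction is then invisible to
the downstream event inference, which is the conventional treatment in
domain-arrangement studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import AnnotationRecord

__all__ = [
    "DomainArrangement",
    "ProteinArchitecture",
    "SpeciesContent",
    "build_architecture",
    "species_content",
]


@dataclass(frozen=True, order=True)
class DomainArrangement:
    """Ordered tuple of domain accessions; identity is the canonical key."""

    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("an arrangement must contain at least one domain")

    @property
    def key(self) -> str:
        return " ".join(self.domains)

    @classmethod
    def from_key(cls, key: str) -> "DomainArrangement":
        return cls(tuple(key.split()))

    def __len__(self) -> int:
        return len(self.domains)

    def concat(self, other: "DomainArrangement") -> "DomainArrangement":
        return DomainArrangement(self.domains + other.domains)

    def __str__(self) -> str:
        return self.key


@dataclass
class ProteinArchitecture:
    """One protein's arrangement plus the envelope coordinates behind it.

    ``instances`` keeps every surviving annotation in envelope order;
    ``position_spans`` maps each arrangement position to the residue span it
    covers (a collapsed run of repeats spans from the first to the last
    instance of the run).  The spans are what the sequence-resolution step
    slices exemplar sequences with.
    """

    protein_id: str
    species: str
    arrangement: DomainArrangement
    instances: list[tuple[str, int, int]] = field(default_factory=list)
    position_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SpeciesContent:
    """Deduplicated arrangement and domain content of one species."""

    species: str
    arrangement_set: set[DomainArrangement] = field(default_factory=set)
    domain_set: set[str] = field(default_factory=set)
    exemplars: dict[DomainArrangement, list[str]] = field(default_factory=dict)


def _resolve_overlaps(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Greedy overlap resolution: better-supported hits win.

    Records are ranked by (E-value asc, bit score desc, start asc) and accepted
    unless they overlap an already accepted envelope.
    """
    ranked = sorted(
        records,
        key=lambda r: (r.e_value, -r.bit_score, r.envelope_start, r.accession),
    )
    accepted: list[AnnotationRecord] = []
    for rec in ranked:
        clash = any(
            rec.envelope_start <= kept.envelope_end
            and kept.envelope_start <= rec.envelope_end
            for kept in accepted
        )
        if not clash:
            accepted.append(rec)
    accepted.sort(key=lambda r: r.envelope_start)
    return accepted


def build_architecture(
    records: Iterable[AnnotationRecord],
    evalue_threshold: Optional[float] = None,
    collapse: bool = True,
    species: str = "",
) -> Optional[ProteinArchitecture]:
    """Build one protein's architecture from its annotation records.

    Records are optionally filtered by E-value, overlapping envelopes are
    resolved (lower E-value wins; ties by higher bit score, then smaller
    start), survivors are sorted by envelope start, and adjacent identical
    accessions are merged into one position when *collapse* is set.  Returns
    ``None`` when nothing survives.
    """
    recs = list(records)
    if not recs:
        return None
    pid = recs[0].protein_id
    if any(r.protein_id != pid for r in recs):
        raise ValueError("build_architecture expects records of a single protein")
    if evalue_threshold is not None:
        recs = [r for r in recs if r.e_value <= evalue_threshold]
    if not recs:
        return None
    survivors = _resolve_overlaps(recs)
    instances = [(r.accession, r.envelope_start, r.envelope_end) for r in survivors]

    domains: list[str] = []
    spans: list[tuple[int, int]] = []
    for acc, start, end in instances:
        if collapse and domains and domains[-1] == acc:
            spans[-1] = (spans[-1][0], end)
        else:
            domains.append(acc)
            spans.append((start, end))
    return ProteinArchitecture(
        protein_id=pid,
        species=species,
        arrangement=DomainArrangement(tuple(domains)),
        instances=instances,
        position_spans=spans,
    )


def species_content(architectures: Iterable[ProteinArchitecture]) -> SpeciesContent:
    """Aggregate one species' architectures into arrangement/domain sets."""
    archs = list(architectures)
    species = archs[0].species if archs else ""
    content = SpeciesContent(species=species)
    for arch in archs:
        content.arrangement_set.add(arch.arrangement)
        content.exemplars.setdefault(arch.arrangement, []).append(arch.protein_id)
        content.domain_set.update(arch.arrangement.domains)
    for carriers in content.exemplars.values():
        carriers.sort()
    return content
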