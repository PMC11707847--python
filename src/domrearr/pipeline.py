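"""End-to-end orchestration: files in, solutions and events out.

Ties the stages together for the CLI and for programmatic use:
read tree + per-species annotations (+ optional proteomes), build
architectures, reconstruct ancestral states, infer events with sequence
resolution when proteomes are available.

Input layout: annotation and FASTA files are named after the tree's leaf
labels inside their directories (``<leaf>.pfamscan`` / ``<leaf>.fasta``,
with a few customary extension variants accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .arrangements import (
    DomainArrangement,
    ProteinArchitecture,
    build_architecture,
    species_content,
)
from .errors import ConsistencyError
from .events import RearrangementEvent, Solution, infer_all
from .io_formats import read_fasta, read_newick, read_pfamscan
from .parsimony import (
    DolloReconstruction,
    FitchReconstruction,
    dollo_reconstruct,
    fitch_reconstruct,
)
from .resolution import ScoringScheme, SequenceProvider, SequenceResolver
from .tree import SpeciesTree

__all__ = ["Dataset", "InferenceResult", "load_dataset", "run_inference"]

_ANNOTATION_EXTS = (".pfamscan", ".txt", ".tsv", ".domtbl")
_FASTA_EXTS = (".fasta", ".fa", ".faa")


@dataclass
class Dataset:
    tree: SpeciesTree
    architectures: dict[str, dict[str, ProteinArchitecture]]
    sequences: dict[str, dict[str, str]]
    leaf_domains: dict[str, set[str]] = field(default_factory=dict)
    leaf_arrangements: dict[str, set[DomainArrangement]] = field(default_factory=dict)

    def provider(self) -> Optional[SequenceProvider]:
        if not any(self.sequences.values()):
            return None
        return SequenceProvider(self.tree, self.architectures, self.sequences)


@dataclass
class InferenceResult:
    dollo: DolloReconstruction
    fitch: FitchReconstruction
    solutions: list[Solution]
    events: list[RearrangementEvent]


def _find_file(directory: Path, leaf: str, extensions) -> Optional[Path]:
    for ext in extensions:
        candidate = directory / f"{leaf}{ext}"
        if candidate.exists():
            return candidate
    return None


def load_dataset(
    tree_path,
    annotation_dir,
    fasta_dir=None,
    evalue_threshold: Optional[float] = None,
    collapse: bool = True,
) -> Dataset:
    """Read tree, annotations and optional proteomes into one dataset.

    Every tree leaf must have an annotation file; a missing one raises
    :class:`ConsistencyError` naming the leaf.  FASTA files are optional —
    without them, ambiguity resolution falls back to the priority order.
    """
    tree = read_newick(tree_path)
    annotation_dir = Path(annotation_dir)
    fasta_dir = Path(fasta_dir) if fasta_dir is not None else None

    architectures: dict[str, dict[str, ProteinArchitecture]] = {}
    sequences: dict[str, dict[str, str]] = {}
    leaf_domains: dict[str, set[str]] = {}
    leaf_arrangements: dict[str, set[DomainArrangement]] = {}

    for leaf in tree.leaf_labels:
        ann_path = _find_file(annotation_dir, leaf, _ANNOTATION_EXTS)
        if ann_path is None:
            raise ConsistencyError(
                f"no annotation file for tree leaf {leaf!r} in {annotation_dir}"
            )
        records = read_pfamscan(ann_path)
        by_protein: dict[str, list] = {}
        for rec in records:
            by_protein.setdefault(rec.protein_id, []).append(rec)
        archs: dict[str, ProteinArchitecture] = {}
        for pid in sorted(by_protein):
            arch = build_architecture(
                by_protein[pid],
                evalue_threshold=evalue_threshold,
                collapse=collapse,
                species=leaf,
            )
            if arch is not None:
                archs[pid] = arch
        architectures[leaf] = archs

        seqs: dict[str, str] = {}
        if fasta_dir is not None:
            fasta_path = _find_file(fasta_dir, leaf, _FASTA_EXTS)
            if fasta_path is not None:
                for rec in read_fasta(fasta_path, leaf):
                    seqs[rec.protein_id] = rec.residues
        sequences[leaf] = seqs

        content = species_content(archs.values())
        leaf_domains[leaf] = content.domain_set
        leaf_arrangements[leaf] = content.arrangement_set

    return Dataset(tree, architectures, sequences, leaf_domains, leaf_arrangements)


def run_inference(
    dataset: Dataset,
    max_steps: int = 3,
    scheme: Optional[ScoringScheme] = None,
) -> InferenceResult:
    """Reconstruct ancestral states and explain every arrangement gain."""
    dollo = dollo_reconstruct(dataset.tree, dataset.leaf_domains)
    fitch = fitch_reconstruct(dataset.tree, dataset.leaf_arrangements)
    provider = dataset.provider()
    resolver = (
        SequenceResolver(provider, scheme or ScoringScheme())
        if provider is not None
        else None
    )
    solutions, events = infer_all(
        dataset.tree, dollo, fitch, seq_resolver=resolver, max_steps=max_steps
    )
    return InferenceResult(dollo, fitch, solutions, events)
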