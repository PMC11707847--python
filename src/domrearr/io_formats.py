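"""Readers and writers for every external format the tool touches.

Supported formats: PfamScan tabular domain annotations (consumed, never
produced by annotation — the simulator emits the same dialect), FASTA
proteomes, Newick species trees, the TSV event table, and iTOL
``DATASET_BINARY`` annotation datasets for tree visualisation.

PfamScan's classic whitespace-delimited text output has 15 columns::

    <seq id> <alignment start> <alignment end> <envelope start> <envelope end>
    <hmm acc> <hmm name> <type> <hmm start> <hmm end> <hmm length>
    <bit score> <E-value> <significance> <clan>

Envelope coordinates (columns 4-5, 1-based inclusive) define domain extent;
only their relative order matters downstream.  Accession version suffixes
(``PF00069.28``) are always stripped: domain identity is the unversioned Pfam
family accession.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from Bio import SeqIO

from .errors import ConsistencyError, InputFormatError
from .tree import SpeciesTree, read_newick  # noqa: F401  (re-exported)

if TYPE_CHECKING:  # pragma: no cover
    from .events import RearrangementEvent, Solution
    from .rates import ProteinHistory

logger = logging.getLogger(__name__)

_ACCESSION_RE = re.compile(r"^PF\d{5}$")
_RESIDUE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")

EVENT_TABLE_COLUMNS = (
    "node",
    "parent",
    "event_type",
    "sources",
    "result",
    "solution_type",
    "solution_id",
    "rank",
)

__all__ = [
    "AnnotationRecord",
    "SequenceRecord",
    "read_pfamscan",
    "read_fasta",
    "filter_longest_isoforms",
    "read_newick",
    "SpeciesTree",
    "write_event_table",
    "read_event_table",
    "write_itol_datasets",
    "EVENT_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One PfamScan hit: a domain family placed on a protein."""

    protein_id: str
    envelope_start: int
    envelope_end: int
    accession: str
    hmm_name: str
    bit_score: float
    e_value: float
    clan: str = ""

    def __post_init__(self) -> None:
        if self.envelope_start < 1 or self.envelope_end < self.envelope_start:
            raise InputFormatError(
                f"{self.protein_id}: bad envelope "
                f"{self.envelope_start}..{self.envelope_end}"
            )
        if not _ACCESSION_RE.match(self.accession):
            raise InputFormatError(
                f"{self.protein_id}: accession {self.accession!r} is not a "
                "Pfam family accession (PF + 5 digits)"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence of one species."""

    protein_id: str
    species: str
    residues: str


def strip_accession_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def read_pfamscan(path) -> list[AnnotationRecord]:
    """Parse a PfamScan tabular annotation file.

    Comment lines (``#``) and blank lines are skipped.  Data lines must carry
    at least 15 whitespace-delimited columns in PfamScan order; fewer columns
    or non-numeric coordinates raise :class:`InputFormatError` naming the
    offending line.
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 15:
                raise InputFormatError(
                    f"{path}:{lineno}: expected >=15 columns, got {len(cols)}"
                )
            try:
                env_start = int(cols[3])
                env_end = int(cols[4])
                bit_score = float(cols[11])
                e_value = float(cols[12])
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}:{lineno}: non-numeric field ({exc})"
                ) from None
            if e_value < 0:
                raise InputFormatError(f"{path}:{lineno}: negative E-value")
            try:
                rec = AnnotationRecord(
                    protein_id=cols[0],
                    envelope_start=env_start,
                    envelope_end=env_end,
                    accession=strip_accession_version(cols[5]),
                    hmm_name=cols[6],
                    bit_score=bit_score,
                    e_value=e_value,
                    clan="" if cols[14] in ("-", "No_clan") else cols[14],
                )
            except InputFormatError as exc:
                raise InputFormatError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    if not records:
        logger.warning("%s: no annotation records found", path)
    return records


def read_fasta(path, species: str) -> list[SequenceRecord]:
    """Read a FASTA proteome; the header token before whitespace is the id."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise InputFormatError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        residues = str(entry.seq).upper()
        if not residues or not _RESIDUE_RE.match(residues):
            raise InputFormatError(
                f"{path}: sequence {pid!r} is empty or contains illegal residues"
            )
        records.append(SequenceRecord(pid, species, residues))
    return records


def filter_longest_isoforms(
    records: Iterable[SequenceRecord],
    gene_of: dict[str, str],
) -> list[SequenceRecord]:
    """Keep the single longest isoform per gene.

    Proteins absent from *gene_of* are treated as singleton genes.  Length
    ties are broken by the lexicographically smallest protein id, so the
    result is deterministic.  Input order of the surviving records is kept.
    """
    best: dict[str, SequenceRecord] = {}
    for rec in records:
        gene = gene_of.get(rec.protein_id, rec.protein_id)
        cur = best.get(gene)
        if (
            cur is None
            or len(rec.residues) > len(cur.residues)
            or (len(rec.residues) == len(cur.residues) and rec.protein_id < cur.protein_id)
        ):
            best[gene] = rec
    keep = {rec.protein_id for rec in best.values()}
    return [rec for rec in records if rec.protein_id in keep]


# ---------------------------------------------------------------------------
# event table


def _fmt_arrangement(arr) -> str:
    return arr.key if arr is not None else "-"


def write_event_table(solutions: Iterable["Solution"], path, tree: Optional[SpeciesTree] = None) -> None:
    """Write solutions as a TSV event table, one row per chain event.

    Row order is deterministic: child-node post-order when a tree is given
    (node id otherwise), then solution id, then rank within the chain.
    """
    rows = []
    for sol in solutions:
        for rank, ev in enumerate(sol.chain, start=1):
            rows.append((sol, rank, ev))
    if tree is not None:
        post_index = {n.id: i for i, n in enumerate(tree.postorder())}
        node_key = lambda node: (post_index.get(node, len(post_index)), node)  # noqa: E731
    else:
        node_key = lambda node: (0, node)  # noqa: E731
    rows.sort(key=lambda r: (node_key(r[2].edge[1]), r[0].id, r[1]))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_TABLE_COLUMNS) + "\n")
        for sol, rank, ev in rows:
            parent, child = ev.edge
            fh.write(
                "\t".join(
                    [
                        child,
                        parent if parent is not None else "-",
                        ev.type.value,
                        "|".join(s.key for s in ev.sources) or "-",
                        _fmt_arrangement(ev.result),
                        sol.solution_type,
                        sol.id,
                        str(rank),
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class EventTableRow:
    event: "RearrangementEvent"
    solution_type: str
    solution_id: str
    rank: int


def read_event_table(path) -> list[EventTableRow]:
    """Read back a TSV event table written by :func:`write_event_table`."""
    from .arrangements import DomainArrangement
    from .events import EventType, RearrangementEvent

    rows: list[EventTableRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EVENT_TABLE_COLUMNS:
            raise InputFormatError(f"{path}: unexpected event-table header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != len(EVENT_TABLE_COLUMNS):
                raise InputFormatError(f"{path}:{lineno}: wrong column count")
            node, parent, etype, sources, result, sol_type, sol_id, rank = cols
            event = RearrangementEvent(
                type=EventType(etype),
                edge=(None if parent == "-" else parent, node),
                sources=tuple(
                    DomainArrangement.from_key(k)
                    for k in (sources.split("|") if sources != "-" else [])
                ),
                result=None if result == "-" else DomainArrangement.from_key(result),
            )
            rows.append(EventTableRow(event, sol_type, sol_id, int(rank)))
    return rows


# ---------------------------------------------------------------------------
# iTOL output


_ITOL_SHAPES = "2"  # filled circle


def write_itol_datasets(
    tracking: Iterable["ProteinHistory"],
    tree: SpeciesTree,
    out_dir,
) -> list[Path]:
    """Write tracking results for iTOL plus plain-text per-protein paths.

    One ``DATASET_BINARY`` file marks, per tracked protein, the tree nodes on
    which its arrangement lineage changed (one data row per protein/node event
    pair).  Additionally one plain-text history file per protein lists its
    steps root→leaf.
    """
    histories = list(tracking)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for hist in histories:
        for step in hist.steps:
            if step.node not in tree:
                raise ConsistencyError(
                    f"tracking references node {step.node!r} absent from tree"
                )

    proteins = [h.protein_id for h in histories]
    written: list[Path] = []
    itol_path = out_dir / "tracked_proteins.itol.txt"
    with open(itol_path, "w") as fh:
        fh.write("DATASET_BINARY\n")
        fh.write("SEPARATOR TAB\n")
        fh.write("DATASET_LABEL\tdomain rearrangement tracking\n")
        fh.write("COLOR\t#d62728\n")
        fh.write("FIELD_SHAPES\t" + "\t".join(_ITOL_SHAPES for _ in proteins) + "\n")
        fh.write("FIELD_LABELS\t" + "\t".join(proteins) + "\n")
        fh.write("DATA\n")
        for col, hist in enumerate(histories):
            for step in hist.steps:
                values = ["-1"] * len(proteins)
                values[col] = "1"
                fh.write(step.node + "\t" + "\t".join(values) + "\n")
    written.append(itol_path)

    for hist in histories:
        p = out_dir / f"{hist.protein_id}.history.txt"
        with open(p, "w") as fh:
            fh.write(f"# protein: {hist.protein_id}  leaf: {hist.leaf}\n")
            fh.write("# path: " + " -> ".join(hist.path) + "\n")
            if hist.ancestral:
                fh.write("# arrangement ancestral at the root (no events on path)\n")
            if hist.has_gaps:
                fh.write("# WARNING: history incomplete (complex solution on path)\n")
            for step in hist.steps:
                if step.solution is not None:
                    sol = step.solution
                    chain = "; ".join(ev.describe() for ev in sol.chain) or "(unexplained)"
                    fh.write(
                        f"{step.node}\t{sol.solution_type}\t{sol.target.key}\t{chain}\n"
                    )
                else:
                    ev = step.event
                    fh.write(
                        f"{step.node}\temergence\t{step.target_key}\t{ev.describe()}\n"
                    )
        written.append(p)
    return written
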