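# Methods

This note documents the models, algorithms, and design choices behind
`domrearr` at the level of detail a user needs to interpret its output and
a maintainer needs to change it safely.

## Input model

Each species contributes a PfamScan-style tabular annotation file (classic
whitespace-delimited text, ≥15 columns) and optionally a FASTA proteome.
Domain identity is the unversioned Pfam family accession (`PF00069.28` →
`PF00069`).  Envelope coordinates (1-based, inclusive) define domain extent;
only their relative order matters downstream.  Per protein, annotations are
optionally filtered by E-value (off by default — Pfam gathering thresholds
are trusted), overlapping envelopes are resolved by a deterministic local
rule (lower E-value wins, ties by higher bit score, then smaller start), and
the surviving domains in N→C order form the protein's *arrangement*.
Adjacent identical accessions are collapsed to one position by default
(tandem-repeat expansion and contraction is then invisible to event
inference, the standard treatment in arrangement studies); the behaviour is
configurable.  Isoform cleanup keeps the longest isoform per gene, ties
broken by smallest protein id.

Species trees are rooted Newick; polytomies are kept as-is.  Internal nodes
are assigned stable identifiers `N1..Nk` in post-order, so all outputs are
reproducible across reads.  Branch lengths are ignored by parsimony.

## Ancestral reconstruction

**Domains — complete Dollo parsimony.**  Each domain family emerges exactly
once, at the LCA of the leaves carrying it.  A node inside the emergence
subtree holds the domain iff at least one of its descendant leaves carries
it; edges on which it disappears are loss edges.  This yields the minimum
loss count compatible with a single gain (verified exhaustively against a
brute-force enumeration of gain placements on all rooted binary trees with
4–6 leaves).  Placing the origin at the LCA even when carriers are scattered
across distant subclades — rather than refusing to commit — is deliberate:
it trades a higher loss count for a defined origin of every family.

**Arrangements — Fitch parsimony.**  Each arrangement is a binary
presence/absence character.  Bottom-up, binary nodes take the intersection
of child state sets when non-empty, otherwise the union; polytomies keep
the states with maximal child support (a Hartigan-style majority vote).
Top-down, an ambiguous root resolves to *absent* and any other ambiguous
node copies its parent.  Gains and losses are read off adjacent resolved
states; per arrangement, gains + losses equals the Fitch parsimony score
(verified against the brute-force minimum over all internal labelings on
the same exhaustive tree set).  The root-tie-to-absent rule prefers
explaining arrangements through observable events on edges over postulating
unobservable ancestral complexity.  Losses of multi-domain arrangements are
recorded for diagnostics but are not one of the six event types.

## Event inference

For every gain edge and target arrangement, single-step candidates are
enumerated from the parent's arrangement set and the child's domain content:

* **fusion** — every ordered pair of parental arrangements whose
  concatenation equals the target;
* **fission** — every parental arrangement with the target as a proper
  prefix/suffix whose complementary part is itself present or co-gained on
  the same edge;
* **terminal loss** — a parental arrangement equal to the target plus
  exactly one terminal domain;
* **terminal gain** — a parental arrangement equal to the target minus one
  terminal domain, where the added domain is in the node's content *and has
  no standalone single-domain arrangement available* — adding a domain that
  also exists as its own protein is, by construction, the fusion with it.
  Without this restriction the canonical two-way ambiguity of AB (fusion
  A + B vs terminal loss ABC − C) would gain spurious extra candidates.
  A terminal gain whose added domain has its Dollo origin on the same edge
  is flagged as carrying a novel domain.
* **single emergence** — a single-domain target whose domain originates on
  this edge is explained directly.

One candidate ⇒ *exact*.  Several ⇒ *inferred*, resolved by sequence (below)
or, when sequences are unavailable or tie, by the fixed priority
fusion > fission > terminal loss > terminal gain, then canonical key.  None
⇒ breadth-first search for all shortest chains of single-step constructors
(fusion of any two available arrangements, truncation of one terminal
domain, terminal addition under the same standalone-domain restriction), up
to `max_steps` (default 3, the length of the canonical worked chain
B + C → BC, A + BC → ABC, ABC − C → AB).  Intermediates must use domains
from the node's content, stay within the longest-parent-plus-two length
bound, be new, and — exploiting that a shortest chain never contains an
unconsumed intermediate — feed a later step; this prunes the search without
losing any minimal chain (checked against a naive exhaustive enumerator on
alphabets ≤5 and depth ≤3).  Chains apply without consuming their sources:
gene duplication before rearrangement is the norm, and presence states are
per-arrangement.  A tie among shortest chains is broken by the alignment
score of the target-creating step, then by a canonical chain key.  If the
search fails the solution is *complex* and its chain is empty.

Event accounting: chain events are deduplicated per node by (type, sources,
result), so a step shared by two chains counts once.  Every Dollo loss edge
contributes a single-loss event.  Every domain family contributes a
single-emergence event at its origin — on the gain edge when the bare
arrangement is gained there, on the virtual edge into the root for
ancestral families — except when the origin is already embodied in a
terminal gain flagged novel (counting both would double-count one
biological event).  Solutions exist only for arrangement gains, so
exact + inferred + multi-step + complex always equals the number of gains.

## Sequence-based resolution

Ambiguity is resolved by optimal **global** pairwise alignment with affine
gap penalties (first gap residue `gap_open` = −10, each further residue
`gap_extend` = −1, in matrix units) under BLOSUM62 by default; any
NCBI-format matrix can be substituted.  Global rather than local alignment
is used because domain instances are already delimited by their envelopes,
so end-to-end similarity is the meaningful signal.  Ancestral nodes carry
no sequences, so an arrangement is represented at a node by an *exemplar*:
the extant carrier protein at the leaf fewest edges away (ties by smallest
protein id), sliced into per-position subsequences by its envelopes (a
collapsed repeat run spans first-to-last instance).  Each candidate's
source positions are mapped onto the target's positions (a fusion's parts
cover prefix and suffix; truncations and extensions map 1:1) and aligned
pairwise; the candidate score is the summed alignment score divided by the
summed column count.  Normalising per column makes a fusion (two shorter
alignments) comparable with a truncation (alignments against a longer
source).  A strict maximum decides; otherwise the priority order applies.
The aligner is verified against hand-computed scores and an independent
quadratic-space Gotoh implementation.

## Rates and tracking

Event and solution counts are aggregated per node and in total, with
percentages rendered to two decimals in the conventional
`count (percent%)` table layout.  Tracking walks a protein's species path
root→leaf and reports every solution whose target is the protein's extant
arrangement or feeds it transitively through chain sources, plus the origin
events of those constituent domains.  All carriers of one arrangement in a
species share the same history: the method is arrangement-based and
performs no paralog resolution or gene-tree reconciliation.  Histories with
a complex solution on the path are emitted with a warning flag rather than
dropped.  iTOL `DATASET_BINARY` output marks, per tracked protein, the
nodes where its lineage changed.

## Synthetic data

The simulator walks the tree from a configurable ancestral arrangement set
(default: four single-domain proteins and two multi-domain proteins of two
and three domains, giving terminal gains domain content that exists only
inside arrangements).  Per branch it draws Poisson event counts per type —
defaults 0.3 fusion, 0.15 fission, 0.15 terminal loss, 0.1 terminal gain,
0.1 emergence, 0.05 single loss per branch, echoing the relative prevalence
reported in real clades (fusion dominant; at this scale single losses rare)
— applies them in a fixed order, and mutates every domain sequence at 0.05
substitutions per residue per branch (domain length 80).  Fresh domains are
minted as `PF9xxxx` accessions; envelopes are emitted as consecutive blocks
separated by 5-residue linkers.  Source arrangements persist through
rearrangements (duplication-first); only a single-domain loss removes an
arrangement and the last copy of its domain.  One fission is recorded as
two ledger events, one per emitted part — exactly how the inference
explains the two gains.  Inapplicable draws are skipped and logged.  A
replay check asserts after every run that the ledger reproduces each leaf's
arrangement set.

`identifiable_mode` restricts proposals so that ground truth is recoverable
in principle: every proposed gain must be the unique single-step explanation
under the inference's own candidate rules (or the fission/terminal-loss tie
on identical source and result, which the priority rule resolves to the true
fission); no arrangement is ever created twice anywhere in the tree
(convergent gains would let Fitch merge and relocate them); no domain is
lost twice (Dollo would collapse the losses onto their common ancestor); and
no single-domain loss sits on a root-child edge (the origin would be
re-placed below the loss).  Junctions that would create adjacent identical
domains are avoided so repeat collapsing cannot blur event identity.

What the simulator does **not** emulate: indels within domains, rate
heterogeneity across branches or sites, annotation error (every domain is
perfectly annotated), clan-level domain similarity, paralogy within a
species (one protein per arrangement), or realistic branch lengths.
Passing recovery tests therefore demonstrates algorithmic correctness under
the model's assumptions, not robustness to annotation noise or alignment
ambiguity in real proteomes.

## Numerical and procedural choices

* All randomness flows through a single seeded NumPy PCG64 generator; equal
  seeds give byte-identical outputs.
* Ties are broken deterministically everywhere: candidate order is
  fusion/fission/terminal loss/terminal gain with canonical source keys;
  chains by serialized key; exemplars by (edge distance, protein id);
  isoforms by (length, id).
* Event scoring in recovery tests matches on (type, edge, sources, result);
  events on the virtual root edge are excluded on both sides, since the
  root state is given, not reconstructed.
* Problem sizes used by the test suite and the acceptance script: exhaustive
  parsimony verification on all rooted binary trees with 4–6 leaves (up to
  945 trees × 64 labelings); end-to-end recovery on a 16-leaf balanced tree;
  200 planted-ambiguity fixtures; 1,000 random alignment pairs of length
  ≤60.  These sizes make the full suite run in seconds while covering every
  code path; the algorithms themselves have no scale-specific constants.

## Known limitations

* Circular permutations and internal (non-terminal) insertions or deletions
  are not modelled as single-step events; such histories surface as
  multi-step or complex solutions.
* Complex solutions are a resolution artifact of sparse taxon sampling;
  denser phylogenies reduce them, the search depth only marginally so.
* The per-column-normalised alignment score has no statistical calibration
  (no E-values); it is a comparative criterion among candidates of one
  ambiguity set only.
* Tracking follows the species path of the extant protein and cannot
  distinguish paralogous carriers of the same arrangement.
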