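"""Ancestral reconstruction of domain content and arrangement presence.

Two parsimony criteria are used side by side, reflecting how differently the
two character types evolve:

* **Dollo parsimony** for single domains.  A domain family is assumed to
  emerge exactly once — convergent re-invention of the same domain from
  unrelated sequence is vanishingly unlikely — so each accession is placed at
  the last common ancestor (LCA) of all leaves carrying it, and every absence
  inside that clade is explained by losses.  This is the *complete* Dollo
  treatment: a domain scattered over distant subclades is still assigned a
  single deep origin rather than being left unexplained.

* **Fitch parsimony** for domain arrangements.  Arrangements recombine from
  existing parts and may well arise independently more than once, so each
  arrangement is treated as a binary presence/absence character and the
  number of state changes is minimised without a single-origin constraint.

Polytomies are handled natively: the Fitch bottom-up pass generalises to a
majority-vote over child state sets (states attaining the maximal child
count are kept), and Dollo is unaffected by node arity.  A root left
ambiguous by Fitch is resolved to *absent*, preferring explanations through
observable gain events over assumed ancestral complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .arrangements import DomainArrangement
from .tree import SpeciesTree, TreeNode

__all__ = ["DolloReconstruction", "FitchReconstruction", "lca", "dollo_reconstruct", "fitch_reconstruct"]

Edge = tuple[str, str]


@dataclass
class DolloReconstruction:
    """Single-origin reconstruction of domain content per node."""

    emergence_node: dict[str, str] = field(default_factory=dict)
    content: dict[str, set[str]] = field(default_factory=dict)
    loss_edges: dict[str, set[Edge]] = field(default_factory=dict)

    def losses_into(self, node_id: str) -> set[str]:
        """Accessions lost on the edge leading into *node_id*."""
        return {
            acc
            for acc, edges in self.loss_edges.items()
            if any(child == node_id for _, child in edges)
        }


@dataclass
class FitchReconstruction:
    """Minimal-change presence/absence reconstruction per arrangement."""

    state: dict[tuple[str, str], bool] = field(default_factory=dict)
    gain_edges: set[tuple[str, str, DomainArrangement]] = field(default_factory=set)
    loss_edges: set[tuple[str, str, DomainArrangement]] = field(default_factory=set)
    arrangements: set[DomainArrangement] = field(default_factory=set)

    def present(self, node_id: str, arrangement: DomainArrangement) -> bool:
        return self.state.get((node_id, arrangement.key), False)

    def arrangements_at(self, node_id: str) -> set[DomainArrangement]:
        return {
            arr
            for arr in self.arrangements
            if self.state.get((node_id, arr.key), False)
        }

    def gains_into(self, node_id: str) -> set[DomainArrangement]:
        return {arr for p, c, arr in self.gain_edges if c == node_id}


def lca(tree: SpeciesTree, leaves) -> str:
    """Last common ancestor of a non-empty set of leaf ids."""
    return tree.lca(leaves).id


def dollo_reconstruct(
    tree: SpeciesTree,
    leaf_domains: Mapping[str, set[str]],
) -> DolloReconstruction:
    """Reconstruct per-node domain content under complete Dollo parsimony.

    Each accession emerges once, at the LCA of the leaves carrying it.  A node
    inside the emergence subtree holds the accession iff at least one of its
    descendant leaves carries it; edges on which the accession disappears are
    recorded as losses.  The resulting loss count is the minimum achievable
    under the single-gain constraint.
    """
    for leaf in tree.leaves:
        if leaf.id not in leaf_domains:
            raise KeyError(f"leaf {leaf.id!r} missing from leaf_domains")

    recon = DolloReconstruction()
    all_accs = sorted(set().union(*leaf_domains.values()) if leaf_domains else set())
    # carriers-below per node, computed once for all accessions
    below: dict[str, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node.id] = set(leaf_domains[node.id])
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= below[child.id]
            below[node.id] = acc
        recon.content[node.id] = set()

    for accession in all_accs:
        carriers = [leaf.id for leaf in tree.leaves if accession in leaf_domains[leaf.id]]
        origin = tree.lca(carriers)
        recon.emergence_node[accession] = origin.id
        recon.loss_edges[accession] = set()
        stack = [origin]
        while stack:
            node = stack.pop()
            if accession in below[node.id]:
                recon.content[node.id].add(accession)
                for child in node.children:
                    if accession in below[child.id]:
                        stack.append(child)
                    else:
                        recon.loss_edges[accession].add((node.id, child.id))
    return recon


def _fitch_bottom_up(node: TreeNode, leaf_state: Mapping[str, bool], sets: dict[str, frozenset[bool]]) -> None:
    for child in node.children:
        _fitch_bottom_up(child, leaf_state, sets)
    if node.is_leaf:
        sets[node.id] = frozenset({leaf_state[node.id]})
        return
    counts = {True: 0, False: 0}
    for child in node.children:
        for state in sets[child.id]:
            counts[state] += 1
    top = max(counts.values())
    sets[node.id] = frozenset(s for s, c in counts.items() if c == top)


def fitch_reconstruct(
    tree: SpeciesTree,
    leaf_arrangements: Mapping[str, set[DomainArrangement]],
) -> FitchReconstruction:
    """Reconstruct per-arrangement presence states under Fitch parsimony.

    Bottom-up: state sets over {present, absent}; binary nodes take the
    intersection of child sets when non-empty, otherwise the union; polytomies
    keep the states with maximal child support.  Top-down: an ambiguous root
    resolves to absent, any other ambiguous node copies its parent's resolved
    state.  Gains and losses are read off adjacent resolved states.
    """
    for leaf in tree.leaves:
        if leaf.id not in leaf_arrangements:
            raise KeyError(f"leaf {leaf.id!r} missing from leaf_arrangements")

    recon = FitchReconstruction()
    universe: set[DomainArrangement] = set()
    for arrs in leaf_arrangements.values():
        universe |= arrs
    recon.arrangements = universe

    for arrangement in sorted(universe):
        leaf_state = {
            leaf.id: arrangement in leaf_arrangements[leaf.id] for leaf in tree.leaves
        }
        sets: dict[str, frozenset[bool]] = {}
        _fitch_bottom_up(tree.root, leaf_state, sets)
        resolved: dict[str, bool] = {}
        for node in tree.preorder():
            options = sets[node.id]
            if len(options) == 1:
                resolved[node.id] = next(iter(options))
            elif node.parent is None:
                resolved[node.id] = False  # ambiguous root -> absent
            else:
                resolved[node.id] = resolved[node.parent.id]
        for node in tree.postorder():
            recon.state[(node.id, arrangement.key)] = resolved[node.id]
            if node.parent is not None:
                p, c = resolved[node.parent.id], resolved[node.id]
                if not p and c:
                    recon.gain_edges.add((node.parent.id, node.id, arrangement))
                elif p and not c:
                    recon.loss_edges.add((node.parent.id, node.id, arrangement))
    return recon
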