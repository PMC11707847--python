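"""Rooted species tree with stable node identifiers.

Newick parsing is delegated to :mod:`dendropy`; the parsed topology is then
converted into a minimal immutable structure tailored to parsimony traversals.
Internal nodes receive deterministic identifiers ``N1, N2, ...`` in post-order,
so repeated reads of the same file always agree.  Branch lengths are retained
for completeness but ignored by every parsimony computation; distances used by
the sequence-resolution step are counted in edges, not in substitutions.

Polytomies are kept as-is: both parsimony engines handle multifurcating nodes
natively, so no arbitrary resolution is ever introduced.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

from .errors import InputFormatError

__all__ = ["TreeNode", "SpeciesTree", "read_newick"]


class TreeNode:
    """One node of a :class:`SpeciesTree`."""

    __slots__ = ("id", "parent", "children", "length", "depth")

    def __init__(self, node_id: str, length: Optional[float] = None) -> None:
        self.id = node_id
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []
        self.length = length
        self.depth = 0  # edges from the root; filled in by SpeciesTree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r})"


class SpeciesTree:
    """A rooted tree whose leaves are species identifiers.

    Construction normalises the topology: internal nodes are renamed
    ``N1..Nk`` in post-order (leaves keep their labels), depths are cached and
    a post-order node list is frozen.  All public traversals are deterministic.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._postorder: list[TreeNode] = []
        self._index: dict[str, TreeNode] = {}
        self._finalize()

    # -- construction -----------------------------------------------------

    def _finalize(self) -> None:
        order: list[TreeNode] = []

        def walk(node: TreeNode, depth: int) -> None:
            node.depth = depth
            for child in node.children:
                child.parent = node
                walk(child, depth + 1)
            order.append(node)

        walk(self.root, 0)
        counter = 0
        for node in order:
            if not node.is_leaf:
                counter += 1
                node.id = f"N{counter}"
        self._postorder = order
        for node in order:
            if node.id in self._index:
                raise InputFormatError(f"duplicate node label {node.id!r}")
            self._index[node.id] = node

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise InputFormatError(f"invalid Newick tree: {exc}") from exc

        def convert(dnode: dendropy.Node) -> TreeNode:
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            node = TreeNode(label, dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.children.append(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        if root.is_leaf:
            raise InputFormatError("tree must contain at least one split")
        return cls(root)

    # -- queries -----------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        return iter(self._postorder)

    def preorder(self) -> Iterator[TreeNode]:
        return iter(reversed(self._postorder))

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.id for n in self.leaves]

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def edges(self) -> Iterator[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs in post-order of the child."""
        for node in self._postorder:
            if node.parent is not None:
                yield node.parent, node

    def subtree_leaves(self, node: TreeNode) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                out.append(cur)
            else:
                stack.extend(reversed(cur.children))
        return out

    def lca(self, leaf_ids: Iterable[str]) -> TreeNode:
        """Deepest node whose subtree contains every given leaf."""
        ids = list(leaf_ids)
        if not ids:
            raise ValueError("lca of an empty leaf set is undefined")
        nodes = [self.node(i) for i in ids]
        for n in nodes:
            if not n.is_leaf:
                raise KeyError(f"{n.id!r} is not a leaf")
        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while a is not b:
                if a.depth >= b.depth:
                    a = a.parent  # type: ignore[assignment]
                else:
                    b = b.parent  # type: ignore[assignment]
            cur = a
        return cur

    def edge_distance(self, a: TreeNode, b: TreeNode) -> int:
        """Number of edges on the path between two nodes."""
        x, y = a, b
        while x is not y:
            if x.depth >= y.depth:
                x = x.parent  # type: ignore[assignment]
            else:
                y = y.parent  # type: ignore[assignment]
        return a.depth + b.depth - 2 * x.depth

    def path_to(self, leaf_id: str) -> list[TreeNode]:
        """Nodes from the root down to the given leaf, inclusive."""
        node = self.node(leaf_id)
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return list(reversed(path))

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.id
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None:
                core += f":{node.length:g}"
            return core

        return fmt(self.root) + ";"


def read_newick(path) -> SpeciesTree:
    """Read a rooted Newick tree from *path*.

    Duplicate leaf labels and syntax errors raise :class:`InputFormatError`.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise InputFormatError(f"{path}: empty tree file")
    return SpeciesTree.from_newick(text)
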