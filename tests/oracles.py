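"""Independent reference implementations used only as test oracles.

Everything here is deliberately written by a different route than the
library: exhaustive enumeration instead of the Fitch/Dollo recursions, a
plain quadratic-space Gotoh dynamic program instead of the aligner, a naive
breadth-first chain enumerator instead of the pruned multi-step search.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np


# ---------------------------------------------------------------------------
# rooted binary tree shapes as nested tuples of leaf labels


def all_rooted_binary_trees(labels: tuple[str, ...]):
    """Every rooted binary labeled tree over *labels* (nested-tuple shapes)."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # the subset containing the first label defines the left child (unordered split)
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            left_labels = (first,) + combo
            right_labels = tuple(x for x in rest if x not in combo)
            if not right_labels:
                continue
            for left in all_rooted_binary_trees(left_labels):
                for right in all_rooted_binary_trees(right_labels):
                    yield (left, right)


def shape_to_newick(shape) -> str:
    def fmt(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(fmt(c) for c in node) + ")"

    return fmt(shape) + ";"


# ---------------------------------------------------------------------------
# brute-force parsimony minima


def _tree_arrays(shape):
    """Flatten a nested-tuple shape into (parent index per node, leaf order).

    Node 0 is the root; leaves carry their label.
    """
    parents: list[int] = []
    leaves: list[tuple[int, str]] = []

    def walk(node, parent: int) -> None:
        idx = len(parents)
        parents.append(parent)
        if isinstance(node, str):
            leaves.append((idx, node))
        else:
            for child in node:
                walk(child, idx)

    walk(shape, -1)
    return parents, leaves


def brute_fitch_min(shape, leaf_state: dict[str, bool]) -> int:
    """Minimal number of edge changes over all internal 0/1 labelings."""
    parents, leaves = _tree_arrays(shape)
    n = len(parents)
    leaf_idx = {i for i, _ in leaves}
    internal = [i for i in range(n) if i not in leaf_idx]
    fixed = {i: int(leaf_state[name]) for i, name in leaves}
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        labels = dict(fixed)
        labels.update(zip(internal, assignment))
        changes = sum(
            1 for i in range(1, n) if labels[i] != labels[parents[i]]
        )
        if best is None or changes < best:
            best = changes
    return best


def brute_dollo_min_losses(shape, carriers: set[str]) -> int:
    """Minimal losses over all single-gain placements covering *carriers*."""
    parents, leaves = _tree_arrays(shape)
    n = len(parents)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[parents[i]].append(i)
    carrier_leaf = {i for i, name in leaves if name in carriers}

    has_carrier = [False] * n
    for i in reversed(range(n)):
        if i in carrier_leaf:
            has_carrier[i] = True
        for c in children[i]:
            if has_carrier[c]:
                has_carrier[i] = True

    def subtree(i: int) -> set[int]:
        out = {i}
        stack = [i]
        while stack:
            j = stack.pop()
            for c in children[j]:
                out.add(c)
                stack.append(c)
        return out

    best = None
    for gain in range(n):
        if not carrier_leaf <= subtree(gain):
            continue
        # forced losses: maximal carrier-free subtrees below the gain node
        losses = 0
        stack = [gain]
        while stack:
            j = stack.pop()
            for c in children[j]:
                if has_carrier[c]:
                    stack.append(c)
                else:
                    losses += 1
        if best is None or losses < best:
            best = losses
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# exhaustive multi-step chain enumeration (small alphabets only)


def _constructor_events(state: frozenset[tuple[str, ...]], content: frozenset[str], max_len: int):
    arrs = sorted(state)
    for x in arrs:
        for y in arrs:
            fused = x + y
            if len(fused) <= max_len and set(fused) <= content:
                yield ("fusion", (x, y), fused)
        if len(x) >= 2:
            yield ("terminal_loss", (x,), x[:-1])
            yield ("terminal_loss", (x,), x[1:])
        if len(x) + 1 <= max_len:
            for d in sorted(content):
                if (d,) in state:
                    continue  # standalone domain: the union is a fusion
                yield ("terminal_gain", (x,), x + (d,))
                yield ("terminal_gain", (x,), (d,) + x)


def enumerate_all_chains(
    target: tuple[str, ...],
    parents: Iterable[tuple[str, ...]],
    content: Iterable[str],
    max_steps: int,
    max_len: int | None = None,
) -> list[tuple]:
    """All shortest chains producing *target*, by naive full enumeration."""
    start = frozenset(parents)
    content = frozenset(content)
    if max_len is None:
        max_len = max([len(a) for a in start] + [len(target)]) + 2

    found: list[tuple] = []

    def consumed(chain: tuple) -> bool:
        # in a shortest chain every intermediate feeds a later step
        for i, (_, _, result) in enumerate(chain[:-1]):
            if not any(result in sources for _, sources, _ in chain[i + 1 :]):
                return False
        return True

    def rec(state: frozenset, chain: list, depth: int) -> None:
        if depth == 0:
            return
        for ev in _constructor_events(state, content, max_len):
            _, _, result = ev
            if result in state:
                continue
            if result == target:
                found.append(tuple(chain + [ev]))
                continue
            rec(state | {result}, chain + [ev], depth - 1)

    for length in range(2, max_steps + 1):
        rec(start, [], length)
        found = [c for c in found if len(c) == length and consumed(c)]
        if found:
            break
    return sorted(set(found))


# ---------------------------------------------------------------------------
# quadratic-space Gotoh global alignment


def gotoh_score(a: str, b: str, matrix, gap_open: float = -10, gap_extend: float = -1) -> float:
    """Affine-gap global alignment score by the classic three-matrix DP.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend``; terminal gaps are penalized.
    """
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (a residue over gap)
    Iy = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(
                M[i - 1, j] + gap_open,
                Ix[i - 1, j] + gap_extend,
                Iy[i - 1, j] + gap_open,
            )
            Iy[i, j] = max(
                M[i, j - 1] + gap_open,
                Iy[i, j - 1] + gap_extend,
                Ix[i, j - 1] + gap_open,
            )
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))
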