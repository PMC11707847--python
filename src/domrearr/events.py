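"""Inference of domain rearrangement events from ancestral reconstructions.

Every arrangement gained on a tree edge (absent in the parent, present in the
child) is explained by exactly one *solution*:

* **exact** — a unique single-step event constructs the arrangement from the
  parent state: a fusion of two parental arrangements, a fission of a
  parental arrangement into persisting parts, the loss of one terminal
  domain, the gain of one terminal domain from the node's domain content, or
  the emergence of a novel single domain at its Dollo origin.
* **inferred** — several single-step candidates exist (AB may arise by
  A + B → AB as well as ABC − C → AB); the ambiguity is resolved by pairwise
  sequence alignment of the candidate domains, falling back to a fixed
  priority order when sequences are unavailable or tie.
* **multi_step** — no single step works, but a shortest chain of single-step
  events (e.g. A + BC → ABC, ABC − C → AB) does, found by exhaustive search
  up to a configurable depth.
* **complex** — nothing within the search bound explains the gain.

Single-domain emergences and losses are read directly off the Dollo
reconstruction and reported as events alongside the rearrangements.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .arrangements import DomainArrangement
from .errors import ChainValidationError
from .parsimony import DolloReconstruction, FitchReconstruction
from .tree import SpeciesTree

__all__ = [
    "EventType",
    "RearrangementEvent",
    "Solution",
    "EVENT_TYPE_ORDER",
    "PRIORITY_ORDER",
    "enumerate_single_step",
    "search_multistep",
    "apply_chain",
    "infer_all",
]


class EventType(enum.Enum):
    FUSION = "fusion"
    FISSION = "fission"
    TERMINAL_LOSS = "terminal_loss"
    TERMINAL_GAIN = "terminal_gain"
    SINGLE_LOSS = "single_loss"
    SINGLE_EMERGENCE = "single_emergence"


#: column order of the rate tables (fusion, fission, terminal loss,
#: terminal gain, single loss, single gain)
EVENT_TYPE_ORDER: tuple[EventType, ...] = (
    EventType.FUSION,
    EventType.FISSION,
    EventType.TERMINAL_LOSS,
    EventType.TERMINAL_GAIN,
    EventType.SINGLE_LOSS,
    EventType.SINGLE_EMERGENCE,
)

#: fallback preference among ambiguous candidates when sequences cannot decide
PRIORITY_ORDER: tuple[EventType, ...] = (
    EventType.FUSION,
    EventType.FISSION,
    EventType.TERMINAL_LOSS,
    EventType.TERMINAL_GAIN,
    EventType.SINGLE_EMERGENCE,
    EventType.SINGLE_LOSS,
)

Edge = tuple[Optional[str], str]


@dataclass(frozen=True)
class RearrangementEvent:
    """One typed rearrangement event placed on a tree edge."""

    type: EventType
    edge: Edge
    sources: tuple[DomainArrangement, ...]
    result: Optional[DomainArrangement]
    novel_domain: Optional[str] = None

    def key(self) -> tuple:
        """Identity used for deduplication and deterministic ordering."""
        return (
            self.type.value,
            self.edge[0] or "",
            self.edge[1],
            tuple(s.key for s in self.sources),
            self.result.key if self.result is not None else "",
        )

    def describe(self) -> str:
        src = " + ".join(s.key for s in self.sources) if self.sources else "-"
        res = self.result.key if self.result is not None else "-"
        return f"{self.type.value}({src} -> {res})"


@dataclass
class Solution:
    """The explanation of one arrangement gain."""

    id: str
    target: DomainArrangement
    edge: Edge
    solution_type: str  # exact | inferred | multi_step | complex
    chain: tuple[RearrangementEvent, ...] = ()
    resolution_scores: dict[tuple, float] = field(default_factory=dict)
    resolved_by: Optional[str] = None  # unique | sequence | priority


def _split_points(target: DomainArrangement) -> Iterable[tuple[tuple[str, ...], tuple[str, ...]]]:
    doms = target.domains
    for i in range(1, len(doms)):
        yield doms[:i], doms[i:]


def enumerate_single_step(
    target: DomainArrangement,
    parent_arrangements: set[DomainArrangement],
    node_domain_content: set[str],
    cogained: set[DomainArrangement] = frozenset(),
    edge: Edge = (None, ""),
    emerging: set[str] = frozenset(),
) -> list[RearrangementEvent]:
    """All single-step events that construct *target* from the parent state.

    Candidate order is deterministic: fusion, fission, terminal loss,
    terminal gain; within a type, sorted by canonical source keys.
    *emerging* holds accessions whose Dollo origin lies on this edge, so a
    terminal gain of one of them is flagged as carrying a novel domain.
    """
    if target in parent_arrangements:
        raise ValueError(f"{target.key!r} is not a gain: present in parent")
    candidates: list[RearrangementEvent] = []
    seen: set[tuple] = set()

    def emit(event: RearrangementEvent) -> None:
        if event.key() not in seen:
            seen.add(event.key())
            candidates.append(event)

    by_domains = {arr.domains: arr for arr in parent_arrangements}
    avail_parts = set(by_domains) | {a.domains for a in cogained}

    fusions, fissions, tlosses, tgains = [], [], [], []
    for prefix, suffix in _split_points(target):
        if prefix in by_domains and suffix in by_domains:
            fusions.append(
                RearrangementEvent(
                    EventType.FUSION,
                    edge,
                    (by_domains[prefix], by_domains[suffix]),
                    target,
                )
            )
    for parent in parent_arrangements:
        pd = parent.domains
        td = target.domains
        if len(pd) > len(td):
            is_prefix = pd[: len(td)] == td
            is_suffix = pd[len(pd) - len(td):] == td
            if is_prefix and pd[len(td):] in avail_parts:
                fissions.append(
                    RearrangementEvent(EventType.FISSION, edge, (parent,), target)
                )
            if is_suffix and pd[: len(pd) - len(td)] in avail_parts:
                fissions.append(
                    RearrangementEvent(EventType.FISSION, edge, (parent,), target)
                )
            if len(pd) == len(td) + 1 and (is_prefix or is_suffix):
                tlosses.append(
                    RearrangementEvent(EventType.TERMINAL_LOSS, edge, (parent,), target)
                )
        if len(pd) == len(td) - 1:
            # adding a domain that exists as a standalone arrangement is a
            # fusion with it, not a terminal gain
            def _addable(d: str) -> bool:
                return d in node_domain_content and (d,) not in avail_parts

            if td[:-1] == pd and _addable(td[-1]):
                tgains.append(
                    RearrangementEvent(
                        EventType.TERMINAL_GAIN,
                        edge,
                        (parent,),
                        target,
                        novel_domain=td[-1] if td[-1] in emerging else None,
                    )
                )
            if td[1:] == pd and _addable(td[0]):
                tgains.append(
                    RearrangementEvent(
                        EventType.TERMINAL_GAIN,
                        edge,
                        (parent,),
                        target,
                        novel_domain=td[0] if td[0] in emerging else None,
                    )
                )

    for bucket in (fusions, fissions, tlosses, tgains):
        for event in sorted(bucket, key=lambda e: e.key()):
            emit(event)
    return candidates


def apply_chain(
    state: set[DomainArrangement],
    chain: Sequence[RearrangementEvent],
) -> set[DomainArrangement]:
    """Apply an event chain to an arrangement set.

    Each event adds its result; sources are never consumed (a fusion's parts
    may persist alongside the fused protein — duplication before fusion is
    the biological norm).  A source missing from the running state raises
    :class:`ChainValidationError`.
    """
    current = set(state)
    for event in chain:
        for source in event.sources:
            if source not in current:
                raise ChainValidationError(
                    f"{event.describe()}: source {source.key!r} unavailable"
                )
        if event.result is not None:
            current.add(event.result)
    return current


def _constructions_of(
    result: DomainArrangement,
    state: set[DomainArrangement],
    content: set[str],
    edge: Edge,
) -> list[RearrangementEvent]:
    """Single-step constructor events producing exactly *result* from *state*."""
    out: list[RearrangementEvent] = []
    seen: set[tuple] = set()
    by_domains = {arr.domains: arr for arr in state}
    rd = result.domains
    for i in range(1, len(rd)):
        if rd[:i] in by_domains and rd[i:] in by_domains:
            ev = RearrangementEvent(
                EventType.FUSION, edge, (by_domains[rd[:i]], by_domains[rd[i:]]), result
            )
            if ev.key() not in seen:
                seen.add(ev.key())
                out.append(ev)
    for arr in state:
        ad = arr.domains
        if len(ad) == len(rd) + 1 and (ad[:-1] == rd or ad[1:] == rd):
            ev = RearrangementEvent(EventType.TERMINAL_LOSS, edge, (arr,), result)
            if ev.key() not in seen:
                seen.add(ev.key())
                out.append(ev)
        if len(ad) == len(rd) - 1:
            if rd[:-1] == ad and rd[-1] in content and (rd[-1],) not in by_domains:
                ev = RearrangementEvent(EventType.TERMINAL_GAIN, edge, (arr,), result)
                if ev.key() not in seen:
                    seen.add(ev.key())
                    out.append(ev)
            if rd[1:] == ad and rd[0] in content and (rd[0],) not in by_domains:
                ev = RearrangementEvent(EventType.TERMINAL_GAIN, edge, (arr,), result)
                if ev.key() not in seen:
                    seen.add(ev.key())
                    out.append(ev)
    return sorted(out, key=lambda e: e.key())


def _expand_results(
    state: set[DomainArrangement],
    content: set[str],
    max_len: int,
) -> list[DomainArrangement]:
    """Every new arrangement creatable in one constructor step from *state*."""
    results: set[DomainArrangement] = set()
    arrs = sorted(state)
    for x in arrs:
        for y in arrs:
            fused = x.domains + y.domains
            if len(fused) <= max_len:
                results.add(DomainArrangement(fused))
        if len(x) >= 2:
            results.add(DomainArrangement(x.domains[:-1]))
            results.add(DomainArrangement(x.domains[1:]))
        if len(x) + 1 <= max_len:
            for d in content:
                if DomainArrangement((d,)) in state:
                    continue
                results.add(DomainArrangement(x.domains + (d,)))
                results.add(DomainArrangement((d,) + x.domains))
    return sorted(r for r in results if r not in state and set(r.domains) <= content)


def search_multistep(
    target: DomainArrangement,
    parent_arrangements: set[DomainArrangement],
    node_domain_content: set[str],
    max_steps: int = 3,
    edge: Edge = (None, ""),
    max_len: Optional[int] = None,
) -> list[tuple[RearrangementEvent, ...]]:
    """All shortest constructor chains (length 2..max_steps) producing *target*.

    Breadth-first over chain lengths: single-step constructors are fusion of
    any two available arrangements, truncation of one terminal domain, and
    terminal addition of a content domain.  Intermediates are restricted to
    domains in the node's content and to a bounded length, must be new, and —
    in a shortest chain — must be consumed by a later step, which prunes the
    enumeration without losing any minimal chain.  Returns ``[]`` when no
    chain within the bound exists.
    """
    if max_steps < 2:
        return []
    if max_len is None:
        longest = max([len(a) for a in parent_arrangements] + [len(target)])
        max_len = longest + 2
    if not set(target.domains) <= node_domain_content:
        return []

    # arrangements usable by the final, target-creating step
    final_sources: set[DomainArrangement] = set()
    td = target.domains
    for i in range(1, len(td)):
        final_sources.add(DomainArrangement(td[:i]))
        final_sources.add(DomainArrangement(td[i:]))
    if len(td) >= 2:
        final_sources.add(DomainArrangement(td[:-1]))
        final_sources.add(DomainArrangement(td[1:]))
    for d in node_domain_content:
        if len(td) + 1 <= max_len:
            final_sources.add(DomainArrangement(td + (d,)))
            final_sources.add(DomainArrangement((d,) + td))

    chains: list[tuple[RearrangementEvent, ...]] = []

    def dfs(
        state: set[DomainArrangement],
        chain: list[RearrangementEvent],
        unused: set[DomainArrangement],
        length: int,
    ) -> None:
        remaining = length - len(chain)
        if remaining == 1:
            for final in _constructions_of(target, state, node_domain_content, edge):
                if unused <= set(final.sources):
                    chains.append(tuple(chain) + (final,))
            return
        if len(unused) > 2 * remaining:
            return
        if remaining == 2:
            # the next intermediate must feed the final step
            results = sorted(
                r
                for r in final_sources
                if r not in state and r != target and set(r.domains) <= node_domain_content
            )
        else:
            results = [r for r in _expand_results(state, node_domain_content, max_len) if r != target]
        for result in results:
            for ev in _constructions_of(result, state, node_domain_content, edge):
                new_unused = (unused - set(ev.sources)) | {result}
                chain.append(ev)
                dfs(state | {result}, chain, new_unused, length)
                chain.pop()

    for length in range(2, max_steps + 1):
        dfs(set(parent_arrangements), [], set(), length)
        if chains:
            break

    unique = {tuple(e.key() for e in c): c for c in chains}
    return [unique[k] for k in sorted(unique)]


def _chain_key(chain: Sequence[RearrangementEvent]) -> tuple:
    return tuple(e.key() for e in chain)


def infer_all(
    tree: SpeciesTree,
    dollo: DolloReconstruction,
    fitch: FitchReconstruction,
    seq_resolver=None,
    max_steps: int = 3,
) -> tuple[list[Solution], list[RearrangementEvent]]:
    """Explain every arrangement gain and derive the single-domain events.

    Returns the per-gain solutions plus the deduplicated event list: chain
    events (an event shared by two chains of the same node is counted once),
    one single-loss event per Dollo loss edge, and the single-domain
    emergences that are not already represented inside a chain.  A domain
    whose emergence edge carries a terminal gain flagged with it as novel is
    considered accounted for by that gain, avoiding double counting; a domain
    emerging at the root is reported on the virtual edge into the root.
    """
    solutions: list[Solution] = []
    emerging_at: dict[str, set[str]] = {}
    for acc, node_id in dollo.emergence_node.items():
        emerging_at.setdefault(node_id, set()).add(acc)

    for node in tree.postorder():
        if node.parent is None:
            continue
        gains = sorted(fitch.gains_into(node.id))
        if not gains:
            continue
        edge: Edge = (node.parent.id, node.id)
        parent_arrs = fitch.arrangements_at(node.parent.id)
        content = dollo.content[node.id]
        emerging = emerging_at.get(node.id, set())
        for target in gains:
            sol_id = f"{node.id}:{target.key}"
            cogained = set(gains) - {target}
            if len(target) == 1 and target.domains[0] in emerging:
                event = RearrangementEvent(
                    EventType.SINGLE_EMERGENCE,
                    edge,
                    (),
                    target,
                    novel_domain=target.domains[0],
                )
                solutions.append(
                    Solution(sol_id, target, edge, "exact", (event,), resolved_by="unique")
                )
                continue
            candidates = enumerate_single_step(
                target, parent_arrs, content, cogained, edge=edge, emerging=emerging
            )
            if len(candidates) == 1:
                solutions.append(
                    Solution(sol_id, target, edge, "exact", (candidates[0],), resolved_by="unique")
                )
                continue
            if len(candidates) > 1:
                if seq_resolver is not None:
                    chosen, scores, how = seq_resolver.resolve(candidates, target)
                else:
                    chosen, scores, how = _priority_resolve(candidates), {}, "priority"
                solutions.append(
                    Solution(
                        sol_id,
                        target,
                        edge,
                        "inferred",
                        (chosen,),
                        resolution_scores=scores,
                        resolved_by=how,
                    )
                )
                continue
            found = search_multistep(
                target, parent_arrs, content, max_steps=max_steps, edge=edge
            )
            if found:
                chain = _pick_chain(found, target, seq_resolver)
                solutions.append(Solution(sol_id, target, edge, "multi_step", chain))
            else:
                solutions.append(Solution(sol_id, target, edge, "complex", ()))

    events = _collect_events(tree, dollo, solutions)
    return solutions, events


def _priority_resolve(candidates: list[RearrangementEvent]) -> RearrangementEvent:
    rank = {t: i for i, t in enumerate(PRIORITY_ORDER)}
    return min(candidates, key=lambda e: (rank[e.type], e.key()))


def _pick_chain(
    chains: list[tuple[RearrangementEvent, ...]],
    target: DomainArrangement,
    seq_resolver,
) -> tuple[RearrangementEvent, ...]:
    if len(chains) == 1:
        return chains[0]
    if seq_resolver is not None:
        scored = []
        for chain in chains:
            s = seq_resolver.score_event(chain[-1], target)
            scored.append((chain, s.normalized if s is not None else None))
        best = [s for _, s in scored if s is not None]
        if best:
            top = max(best)
            leaders = [c for c, s in scored if s == top]
            if len(leaders) == 1:
                return leaders[0]
            return min(leaders, key=_chain_key)
    return min(chains, key=_chain_key)


def _collect_events(
    tree: SpeciesTree,
    dollo: DolloReconstruction,
    solutions: list[Solution],
) -> list[RearrangementEvent]:
    by_key: dict[tuple, RearrangementEvent] = {}
    for sol in solutions:
        for event in sol.chain:
            by_key.setdefault(event.key(), event)

    emergence_covered: set[str] = set()
    for event in by_key.values():
        if event.type is EventType.SINGLE_EMERGENCE and event.novel_domain:
            emergence_covered.add(event.novel_domain)
        if event.type is EventType.TERMINAL_GAIN and event.novel_domain:
            emergence_covered.add(event.novel_domain)

    for acc in sorted(dollo.emergence_node):
        if acc in emergence_covered:
            continue
        node = tree.node(dollo.emergence_node[acc])
        edge: Edge = (node.parent.id if node.parent else None, node.id)
        event = RearrangementEvent(
            EventType.SINGLE_EMERGENCE,
            edge,
            (),
            DomainArrangement((acc,)),
            novel_domain=acc,
        )
        by_key.setdefault(event.key(), event)

    for acc in sorted(dollo.loss_edges):
        for edge in sorted(dollo.loss_edges[acc]):
            event = RearrangementEvent(
                EventType.SINGLE_LOSS,
                edge,
                (DomainArrangement((acc,)),),
                None,
            )
            by_key.setdefault(event.key(), event)

    post_index = {n.id: i for i, n in enumerate(tree.postorder())}
    type_rank = {t: i for i, t in enumerate(EVENT_TYPE_ORDER)}
    return sorted(
        by_key.values(),
        key=lambda e: (post_index.get(e.edge[1], len(post_index)), type_rank[e.type], e.key()),
    )
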