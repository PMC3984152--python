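"""Cycle calculus on automaton transition graphs.

The central objects are *closed walks* (rooted state sequences along
transitions), *cycles* (state sets admitting a closed path visiting
precisely those states), and the *constitutive decomposition* of a closed
walk into vertex-simple cycles via a stack algorithm.

Two cycle universes are supported, because the formal notion and the
operational census differ:

``strongly_connected``
    every state set whose induced subgraph is strongly connected (a closed
    walk may reuse transitions), the formal definition;
``trail_support``
    state sets realisable as the support of an *edge-distinct* closed walk
    (a closed trail) — the operational notion behind per-state cycle
    censuses, strictly contained in the former.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

__all__ = [
    "ClosedWalk",
    "Cycle",
    "CycleCapExceeded",
    "TransitionGraph",
    "sccs",
    "simple_cycles",
    "closed_walks_from",
    "constitutive_decomposition",
    "cycles_as_sets",
    "accessible",
    "includes",
    "communicate",
    "attractors",
]


class CycleCapExceeded(RuntimeError):
    """Raised when an enumeration exceeds its configured cap."""


@dataclass(frozen=True)
class ClosedWalk:
    """A rooted closed walk: a state sequence with ``first == last``.

    ``letters`` (optional) carries one input letter per step, making the
    walk a labelled trail through a deterministic automaton graph.
    """

    sequence: tuple[int, ...]
    letters: Optional[tuple[tuple[int, ...], ...]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 2 or self.sequence[0] != self.sequence[-1]:
            raise ValueError("a closed walk needs first == last and >= 1 step")
        if self.letters is not None and len(self.letters) != len(self.sequence) - 1:
            raise ValueError("need one letter per step")

    @property
    def root(self) -> int:
        return self.sequence[0]

    def __len__(self) -> int:
        return len(self.sequence) - 1

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.sequence)

    def is_vertex_simple(self) -> bool:
        body = self.sequence[:-1]
        return len(set(body)) == len(body)

    @property
    def period_states(self) -> tuple[int, ...]:
        """The states of one traversal, endpoint counted once."""
        return self.sequence[:-1]


@dataclass(frozen=True)
class Cycle:
    """A cycle in the automaton sense: a state set plus a witness walk.

    The witness visits precisely ``state_set``; for vertex-simple cycles the
    witness is essentially unique up to rotation.
    """

    state_set: frozenset[int]
    witness: ClosedWalk

    def __post_init__(self) -> None:
        if self.witness.support != self.state_set:
            raise ValueError("witness must visit precisely the state set")

    def __len__(self) -> int:
        return len(self.state_set)

    def is_simple(self) -> bool:
        return self.witness.is_vertex_simple()

    def __contains__(self, state: int) -> bool:
        return state in self.state_set


class TransitionGraph:
    """A deterministic labelled transition graph over integer states.

    Thin wrapper around the edge list ``(src, dst, letter)`` with the
    derived views the cycle machinery needs (collapsed successors,
    letter-labelled successors, a networkx ``DiGraph``).
    """

    def __init__(self, edges: Iterable[tuple[int, int, tuple[int, ...]]],
                 nodes: Optional[Iterable[int]] = None):
        self.edges = sorted(set(edges))
        self.nodes = sorted({e[0] for e in self.edges} | {e[1] for e in self.edges}
                            | (set(nodes) if nodes is not None else set()))
        self._succ_lab: dict[int, list[tuple[int, tuple[int, ...]]]] = {v: [] for v in self.nodes}
        for a, b, letter in self.edges:
            self._succ_lab[a].append((b, letter))
        self._succ: dict[int, list[int]] = {
            v: sorted({b for b, _ in lst}) for v, lst in self._succ_lab.items()}
        self._nx = nx.DiGraph()
        self._nx.add_nodes_from(self.nodes)
        self._nx.add_edges_from((a, b) for a, b, _ in self.edges)

    def successors(self, v: int) -> list[int]:
        return self._succ[v]

    def labelled_successors(self, v: int) -> list[tuple[int, tuple[int, ...]]]:
        return sorted(self._succ_lab[v])

    def as_networkx(self) -> nx.DiGraph:
        return self._nx

    def subgraph(self, states: Iterable[int]) -> "TransitionGraph":
        s = set(states)
        return TransitionGraph(
            ((a, b, l) for a, b, l in self.edges if a in s and b in s), nodes=s)

    def letters_between(self, a: int, b: int) -> list[tuple[int, ...]]:
        return sorted(l for (bb, l) in self._succ_lab[a] if bb == b)


def sccs(graph: TransitionGraph) -> list[frozenset[int]]:
    """Strongly connected components in condensation (topological) order.

    Singletons without a self-loop are still returned (they carry no cycle);
    use :func:`scc_is_cyclic` to filter.
    """
    g = graph.as_networkx()
    comp = list(nx.strongly_connected_components(g))
    cond = nx.condensation(g, scc=comp)
    order = nx.topological_sort(cond)
    return [frozenset(cond.nodes[i]["members"]) for i in order]


def scc_is_cyclic(graph: TransitionGraph, comp: frozenset[int]) -> bool:
    if len(comp) > 1:
        return True
    (v,) = comp
    return v in graph.successors(v)


def simple_cycles(graph: TransitionGraph, through: Optional[int] = None,
                  cap: int = 1_000_000) -> list[Cycle]:
    """All vertex-simple directed cycles (Johnson's algorithm).

    Parallel letter-labelled edges over the same vertex sequence count once
    at the state-set level; the returned witness carries the
    lexicographically smallest letter choice per step.
    """
    out = []
    for seq in nx.simple_cycles(graph.as_networkx()):
        if through is not None and through not in seq:
            continue
        if len(out) >= cap:
            raise CycleCapExceeded(f"more than {cap} simple cycles")
        # rotate to smallest state for a canonical witness
        i = seq.index(min(seq))
        seq = seq[i:] + seq[:i]
        closed = tuple(seq) + (seq[0],)
        letters = tuple(graph.letters_between(a, b)[0]
                        for a, b in zip(closed, closed[1:]))
        out.append(Cycle(frozenset(seq), ClosedWalk(closed, letters)))
    out.sort(key=lambda c: (len(c.state_set), sorted(c.state_set)))
    return out


def closed_walks_from(graph: TransitionGraph, root: int,
                      mode: str = "edge_distinct_rooted",
                      cap: int = 2_000_000) -> list[ClosedWalk]:
    """Edge-distinct closed walks (trails) rooted at ``root``.

    Modes
    -----
    ``edge_distinct_rooted``
        every rooted labelled trail, counted as a rooted edge sequence;
    ``edge_distinct_collapsed``
        trails on the collapsed graph (parallel letter edges merged);
    ``support_sets``
        one representative trail per distinct support (the first found in
        depth-first order) — the census convention for cycles-as-sets.
    """
    if mode not in ("edge_distinct_rooted", "edge_distinct_collapsed", "support_sets"):
        raise ValueError(f"unknown walk mode {mode!r}")
    collapsed = mode in ("edge_distinct_collapsed", "support_sets")
    res: list[ClosedWalk] = []
    seen_supports: set[frozenset[int]] = set()
    used: set = set()
    seq = [root]
    letters: list = []

    def emit() -> None:
        if len(res) >= cap:
            raise CycleCapExceeded(f"more than {cap} closed walks from {root}")
        walk = ClosedWalk(tuple(seq), None if collapsed else tuple(letters))
        if mode == "support_sets":
            sup = walk.support
            if sup in seen_supports:
                return
            seen_supports.add(sup)
        res.append(walk)

    def dfs(v: int) -> None:
        if collapsed:
            options = [(w, None) for w in graph.successors(v)]
        else:
            options = graph.labelled_successors(v)
        for w, letter in options:
            e = (v, w) if collapsed else (v, w, letter)
            if e in used:
                continue
            used.add(e)
            seq.append(w)
            if not collapsed:
                letters.append(letter)
            if w == root:
                emit()
            dfs(w)
            seq.pop()
            if not collapsed:
                letters.pop()
            used.remove(e)

    dfs(root)
    return res


def constitutive_decomposition(walk: ClosedWalk) -> list[Cycle]:
    """Split a closed walk into vertex-simple constitutive cycles.

    Stack algorithm: push states along the walk; when the next state is
    already on the stack, pop the enclosed segment as one constitutive
    cycle.  The final return to the root closes the last cycle.  Every step
    of the walk lands in exactly one constitutive cycle, so the cycle
    lengths sum to the walk length.
    """
    stack: list[int] = [walk.sequence[0]]
    pos = {walk.sequence[0]: 0}
    pending: list = []  # letters of edges not yet assigned to a cycle
    out: list[Cycle] = []
    for k, s in enumerate(walk.sequence[1:]):
        pending.append(walk.letters[k] if walk.letters is not None else None)
        if s in pos:
            i = pos[s]
            cyc_states = tuple(stack[i:]) + (s,)
            ncyc = len(cyc_states) - 1
            seg = pending[len(pending) - ncyc:]
            del pending[len(pending) - ncyc:]
            lets = None if walk.letters is None else tuple(seg)
            out.append(Cycle(frozenset(cyc_states[:-1]), ClosedWalk(cyc_states, lets)))
            for v in stack[i + 1:]:
                del pos[v]
            del stack[i + 1:]
        else:
            pos[s] = len(stack)
            stack.append(s)
    return out


def _induced_strongly_connected(members: Sequence[int],
                                succ: dict[int, list[int]]) -> bool:
    memset = set(members)
    if len(members) == 1:
        (v,) = members
        return v in succ[v]
    start = members[0]
    stack, seen = [start], {start}
    while stack:
        v = stack.pop()
        for w in succ[v]:
            if w in memset and w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != len(members):
        return False
    pred: dict[int, list[int]] = {v: [] for v in members}
    for v in members:
        for w in succ[v]:
            if w in memset:
                pred[w].append(v)
    stack, seen = [start], {start}
    while stack:
        v = stack.pop()
        for w in pred[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(members)


def _canonical_walk(graph: TransitionGraph, states: frozenset[int]) -> ClosedWalk:
    """A deterministic closed walk visiting precisely ``states``.

    Greedy cover: from the smallest state, repeatedly walk (shortest path
    inside the set, ties broken by state number) to the smallest unvisited
    state, then close back to the start.
    """
    sub = {v: [w for w in graph.successors(v) if w in states] for v in states}
    start = min(states)

    def shortest(a: int, targets: set[int]) -> list[int]:
        frontier = [a]
        parent = {a: None}
        while frontier:
            nxt = []
            for v in frontier:
                for w in sub[v]:
                    if w not in parent:
                        parent[w] = v
                        nxt.append(w)
                    if w in targets and (w != a or parent[w] is not None):
                        pass
            hit = sorted(t for t in targets if t in parent and t != a)
            if hit:
                path = [hit[0]]
                while path[-1] != a:
                    path.append(parent[path[-1]])
                return path[::-1]
            frontier = sorted(nxt)
        raise ValueError("set is not strongly connected")

    seq = [start]
    unvisited = set(states) - {start}
    while unvisited:
        path = shortest(seq[-1], unvisited)
        seq.extend(path[1:])
        unvisited -= set(path)
    if len(states) == 1:
        seq.append(start)
    elif seq[-1] != start:
        seq.extend(shortest(seq[-1], {start})[1:])
    return ClosedWalk(tuple(seq))


def cycles_as_sets(graph: TransitionGraph, universe: str = "trail_support",
                   cap: int = 2_000_000) -> list[Cycle]:
    """Enumerate all cycles (state sets) of the graph.

    ``trail_support``: supports of edge-distinct closed walks, with the
    discovering trail as witness.  ``strongly_connected``: every state set
    inducing a strongly connected subgraph, with a canonical greedy witness
    (closed walks may reuse transitions under the formal cycle definition).
    """
    if universe == "trail_support":
        seen: dict[frozenset[int], ClosedWalk] = {}
        for comp in sccs(graph):
            if not scc_is_cyclic(graph, comp):
                continue
            sub = graph.subgraph(comp)
            for root in sorted(comp):
                for w in closed_walks_from(sub, root, mode="support_sets", cap=cap):
                    seen.setdefault(w.support, w)
        return [Cycle(s, w) for s, w in
                sorted(seen.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))]
    if universe == "strongly_connected":
        out = []
        for comp in sccs(graph):
            members = sorted(comp)
            if len(members) > 24:
                raise CycleCapExceeded(
                    f"SCC of size {len(members)}: subset enumeration infeasible")
            sub = graph.subgraph(comp)
            succ = {v: sub.successors(v) for v in members}
            n = len(members)
            for mask in range(1, 1 << n):
                sel = [members[i] for i in range(n) if mask >> i & 1]
                if _induced_strongly_connected(sel, succ):
                    st = frozenset(sel)
                    out.append(Cycle(st, _canonical_walk(graph, st)))
                    if len(out) > cap:
                        raise CycleCapExceeded(f"more than {cap} cycles")
        out.sort(key=lambda c: (len(c.state_set), sorted(c.state_set)))
        return out
    raise ValueError(f"unknown cycle universe {universe!r}")


def accessible(a: Cycle, b: Cycle, graph: TransitionGraph) -> bool:
    """True iff some state of ``b`` is reachable from some state of ``a``."""
    g = graph.as_networkx()
    targets = set(b.state_set)
    if targets & set(a.state_set):
        return True
    for s in a.state_set:
        if targets & nx.descendants(g, s):
            return True
    return False


def includes(a: Cycle, b: Cycle) -> bool:
    """True iff the state set of ``b`` contains the state set of ``a``."""
    return a.state_set <= b.state_set


def communicate(a: Cycle, b: Cycle, graph: TransitionGraph) -> bool:
    """Mutual accessibility — equivalently, same strongly connected component."""
    return accessible(a, b, graph) and accessible(b, a, graph)


def attractors(net, reachable_only: bool = True, universe: str = "strongly_connected",
               cap: int = 2_000_000) -> list[Cycle]:
    """The realisable attractors of a network: cycles of its automaton graph
    reachable from the all-quiet initial state."""
    from .automata import network_graph

    graph = network_graph(net, reachable_only=reachable_only)
    return cycles_as_sets(graph, universe=universe, cap=cap)
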