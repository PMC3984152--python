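"""Attractor-based complexity degrees.

The degree of a network is the length of a maximal alternating or
co-alternating structure over the cycles of its automaton:

* for Büchi automata (output-layer networks), *chains* — sequences of
  cycles of strictly alternating success linked by one-way accessibility,
  with an ω-chain realised by two communicating cycles of opposite type;
* for Muller automata (freely typed networks), *trees* — strictly
  increasing inclusion sequences of alternating type inside a strongly
  connected component, extended across components by one-way accessibility.

Degrees are ordinals below ω^ω in Cantor normal form.  The finite fragment
and the ω-chain detection are exact; transfinite tree levels are reported
as explicit lower bounds built from branch points of the condensation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .automata import BuchiAutomaton, MullerAutomaton
from .cycles import (Cycle, TransitionGraph, cycles_as_sets, sccs,
                     scc_is_cyclic, simple_cycles)
from .typing_rules import MEANINGFUL, SPURIOUS, TypeAssignment

__all__ = [
    "OrdinalDegree",
    "AlternatingStructure",
    "ordinal_compare",
    "max_chain",
    "max_tree",
    "rnn_degree",
    "complete_degree",
    "buchi_segment_check",
]


@dataclass(frozen=True)
class OrdinalDegree:
    """An ordinal < ω^ω in Cantor normal form, with degree metadata.

    ``cnf`` maps exponent k to a positive coefficient n_k, denoting
    Σ ω^k·n_k; comparison is lexicographic on descending exponents.
    ``status`` is ``"exact"`` or ``"lower_bound"`` (transfinite tree search
    beyond the implemented recursion).
    """

    cnf: tuple[tuple[int, int], ...]
    self_dual: bool = False
    kind: Optional[str] = None  # alternating | co_alternating | None
    witness: Optional["AlternatingStructure"] = None
    status: str = "exact"

    def __post_init__(self) -> None:
        exps = [e for e, _ in self.cnf]
        if exps != sorted(exps, reverse=True) or len(set(exps)) != len(exps):
            raise ValueError("CNF must have strictly descending exponents")
        if any(c <= 0 for _, c in self.cnf):
            raise ValueError("CNF coefficients must be positive")

    @classmethod
    def finite(cls, n: int, **kw) -> "OrdinalDegree":
        return cls(((0, n),) if n else (), **kw)

    @classmethod
    def omega(cls, coeff: int = 1, plus: int = 0, **kw) -> "OrdinalDegree":
        cnf = ((1, coeff),) + (((0, plus),) if plus else ())
        return cls(cnf, **kw)

    @property
    def is_finite(self) -> bool:
        return all(e == 0 for e, _ in self.cnf)

    @property
    def finite_value(self) -> int:
        if not self.is_finite:
            raise ValueError("not a finite ordinal")
        return self.cnf[0][1] if self.cnf else 0

    def pretty(self) -> str:
        if not self.cnf:
            return "0"
        parts = []
        for e, c in self.cnf:
            if e == 0:
                parts.append(str(c))
            elif e == 1:
                parts.append(f"ω·{c}" if c != 1 else "ω")
            else:
                parts.append(f"ω^{e}·{c}" if c != 1 else f"ω^{e}")
        return "+".join(parts)

    def __repr__(self) -> str:  # compact for test output
        flags = []
        if self.kind:
            flags.append(self.kind)
        if self.self_dual:
            flags.append("self-dual")
        if self.status != "exact":
            flags.append(self.status)
        return f"OrdinalDegree({self.pretty()}{', ' + ', '.join(flags) if flags else ''})"


def ordinal_compare(a: OrdinalDegree, b: OrdinalDegree) -> str:
    """Lexicographic CNF comparison: returns 'lt', 'eq' or 'gt'."""
    pa, pb = list(a.cnf), list(b.cnf)
    while pa and pb:
        (ea, ca), (eb, cb) = pa[0], pb[0]
        if ea != eb:
            return "gt" if ea > eb else "lt"
        if ca != cb:
            return "gt" if ca > cb else "lt"
        pa, pb = pa[1:], pb[1:]
    if pa:
        return "gt"
    if pb:
        return "lt"
    return "eq"


@dataclass(frozen=True)
class AlternatingStructure:
    """An alternating or co-alternating chain/tree witness.

    Cycles are listed chain-start first (innermost first for inclusion
    trees); ``relations[i]`` tags how cycle i+1 relates to cycle i
    (``included`` | ``accessible`` | ``communicating``).  A leading cycle
    that does not alternate with the chain (the census' C0) is recorded in
    ``excluded_prefix`` but not counted in the length.
    """

    kind: str
    cycles: tuple[Cycle, ...]
    types: tuple[str, ...]
    relations: tuple[str, ...]
    excluded_prefix: tuple[Cycle, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("alternating", "co_alternating"):
            raise ValueError(f"bad kind {self.kind!r}")
        if len(self.types) != len(self.cycles):
            raise ValueError("one type per cycle")
        if self.cycles and len(self.relations) != len(self.cycles) - 1:
            raise ValueError("one relation per consecutive pair")
        first = MEANINGFUL if self.kind == "alternating" else SPURIOUS
        if self.cycles and self.types[0] != first:
            raise ValueError(f"{self.kind} structure must start {first}")
        for t, u in zip(self.types, self.types[1:]):
            if t == u:
                raise ValueError("types must strictly alternate")

    def __len__(self) -> int:
        return len(self.cycles)


# ---------------------------------------------------------------------------
# Büchi chains

def _scc_type_info(graph: TransitionGraph, finals: frozenset[int]):
    """Per cyclic SCC: does it host successful / non-successful cycles?"""
    comps = sccs(graph)
    info = []
    for comp in comps:
        if not scc_is_cyclic(graph, comp):
            info.append((comp, False, False))
            continue
        has_succ = bool(comp & finals)
        rest = comp - finals
        has_nonsucc = False
        if rest:
            sub = graph.subgraph(rest)
            for c in sccs(sub):
                if scc_is_cyclic(sub, c):
                    has_nonsucc = True
                    break
        info.append((comp, has_succ, has_nonsucc))
    return info


def _some_cycle(graph: TransitionGraph, comp: frozenset[int],
                finals: frozenset[int], successful: bool) -> Cycle:
    sub = graph.subgraph(comp)
    if successful:
        for c in simple_cycles(sub):
            if c.state_set & finals:
                return c
    else:
        avoid = sub.subgraph(comp - finals)
        for c in sccs(avoid):
            if scc_is_cyclic(avoid, c):
                return simple_cycles(avoid.subgraph(c))[0]
    raise ValueError("no such cycle")  # guarded by _scc_type_info


def max_chain(buchi: BuchiAutomaton, cap: int = 1_000_000):
    """Maximal alternating and co-alternating chain lengths of a Büchi automaton.

    Returns ``(alt, co_alt, witness)`` where ``alt``/``co_alt`` are the
    longest chain lengths starting with a successful / non-successful
    cycle (as :class:`OrdinalDegree`), and ``witness`` realises the longer
    one.  Two communicating cycles of opposite type (necessarily in one
    SCC) yield the ω-chain.
    """
    graph = buchi.graph()
    info = _scc_type_info(graph, buchi.finals)

    for comp, hs, hn in info:
        if hs and hn:  # opposite types communicate inside one SCC
            cs = _some_cycle(graph, comp, buchi.finals, True)
            cn = _some_cycle(graph, comp, buchi.finals, False)
            w = AlternatingStructure(
                "alternating", (cs, cn), (MEANINGFUL, SPURIOUS), ("communicating",))
            om = OrdinalDegree.omega()
            return om, om, w

    # condensation DAG over cyclic SCCs with a single type each
    comp_ids = {i: comp for i, (comp, hs, hn) in enumerate(info)}
    type_of = {i: (MEANINGFUL if hs else (SPURIOUS if hn else None))
               for i, (comp, hs, hn) in enumerate(info)}
    node_of_state = {}
    for i, comp in comp_ids.items():
        for s in comp:
            node_of_state[s] = i
    dag = nx.DiGraph()
    dag.add_nodes_from(comp_ids)
    for a, b, _ in graph.edges:
        u, v = node_of_state[a], node_of_state[b]
        if u != v:
            dag.add_edge(u, v)

    # dp[node][(start,last)] -> best chain (list of scc ids), pass-through allowed
    best: dict[tuple[str, str], list[int]] = {}
    dp: dict[int, dict[tuple[str, str], list[int]]] = {}
    for v in nx.topological_sort(dag):
        cur: dict[tuple[str, str], list[int]] = {}
        for u in dag.predecessors(v):
            for key, chain in dp[u].items():
                if key not in cur or len(chain) > len(cur[key]):
                    cur[key] = chain
        t = type_of[v]
        if t is not None:
            upd = {}
            for start in (MEANINGFUL, SPURIOUS):
                base = [v] if t == start else None
                prev = cur.get((start, _other(t)))
                cand = (prev + [v]) if prev else base
                if cand is not None:
                    key = (start, t)
                    if key not in cur or len(cand) > len(cur[key]):
                        upd[key] = cand
            cur.update(upd)
        dp[v] = cur
        for key, chain in cur.items():
            if key not in best or len(chain) > len(best[key]):
                best[key] = chain

    def best_for(start: str) -> list[int]:
        out: list[int] = []
        for (s, _), chain in best.items():
            if s == start and len(chain) > len(out):
                out = chain
        return out

    alt_chain = best_for(MEANINGFUL)
    co_chain = best_for(SPURIOUS)

    def build(chain: list[int], kind: str) -> Optional[AlternatingStructure]:
        if not chain:
            return None
        cycles, types = [], []
        for i in chain:
            t = type_of[i]
            cycles.append(_some_cycle(graph, comp_ids[i], buchi.finals,
                                      t == MEANINGFUL))
            types.append(t)
        return AlternatingStructure(kind, tuple(cycles), tuple(types),
                                    ("accessible",) * (len(cycles) - 1))

    alt = OrdinalDegree.finite(len(alt_chain))
    co = OrdinalDegree.finite(len(co_chain))
    witness = (build(alt_chain, "alternating")
               if len(alt_chain) >= len(co_chain)
               else build(co_chain, "co_alternating"))
    return alt, co, witness


def _other(t: str) -> str:
    return SPURIOUS if t == MEANINGFUL else MEANINGFUL


# ---------------------------------------------------------------------------
# Muller trees

def _typed_cycles_by_scc(graph: TransitionGraph, typer, universe: str, cap: int):
    out: dict[frozenset[int], list[tuple[Cycle, str]]] = {}
    for comp in sccs(graph):
        if not scc_is_cyclic(graph, comp):
            out[comp] = []
            continue
        sub = graph.subgraph(comp)
        cycles = cycles_as_sets(sub, universe=universe, cap=cap)
        out[comp] = [(c, typer(c)) for c in cycles]
    return out


def _segment_dp(cycles: list[tuple[Cycle, str]]):
    """Longest alternating strict-inclusion chains within one SCC.

    Returns ``seg[(start, last)] = chain`` (list of (Cycle, type),
    innermost first).
    """
    ordered = sorted(cycles, key=lambda ct: (len(ct[0].state_set),
                                             sorted(ct[0].state_set)))
    dp: list[dict[str, list[tuple[Cycle, str]]]] = []
    seg: dict[tuple[str, str], list[tuple[Cycle, str]]] = {}
    for i, (c, t) in enumerate(ordered):
        cell: dict[str, list] = {}
        for start in (MEANINGFUL, SPURIOUS):
            best_prev: list = []
            for j in range(i):
                d, u = ordered[j]
                if u != t and d.state_set < c.state_set:
                    prev = dp[j].get(start)
                    if prev and len(prev) > len(best_prev):
                        best_prev = prev
            if best_prev:
                cell[start] = best_prev + [(c, t)]
            elif t == start:
                cell[start] = [(c, t)]
        dp.append(cell)
        for start, chain in cell.items():
            key = (start, t)
            if key not in seg or len(chain) > len(seg[key]):
                seg[key] = chain
    return seg


def max_tree(muller=None, *, graph: Optional[TransitionGraph] = None,
             assignment: Optional[TypeAssignment] = None,
             universe: str = "strongly_connected", cap: int = 2_000_000):
    """Maximal alternating / co-alternating tree lengths of a Muller automaton.

    Finite lengths are exact: strictly increasing alternating inclusion
    chains within each SCC, concatenated across the condensation through
    one-way accessibility with alternation at the junctions.  Transfinite
    levels are reported as a lower bound ω·m when m nested branch points of
    the condensation admit both-type continuations.
    """
    if muller is not None:
        graph = muller.graph()
        typer = lambda c: MEANINGFUL if muller.successful(c.state_set) else SPURIOUS
    else:
        if graph is None or assignment is None:
            raise ValueError("need either a Muller automaton or graph+assignment")
        typer = assignment.type_of

    by_scc = _typed_cycles_by_scc(graph, typer, universe, cap)
    comps = list(by_scc)
    seg = {comp: _segment_dp(cycles) for comp, cycles in by_scc.items()}

    node_of_state = {}
    for i, comp in enumerate(comps):
        for s in comp:
            node_of_state[s] = i
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(comps)))
    for a, b, _ in graph.edges:
        u, v = node_of_state[a], node_of_state[b]
        if u != v:
            dag.add_edge(u, v)

    # condensation DP with pass-through; chains are lists of
    # (cycle, type, relation-to-previous)
    Chain = list
    best: dict[tuple[str, str], Chain] = {}
    dp: dict[int, dict[tuple[str, str], Chain]] = {}
    for v in nx.topological_sort(dag):
        cur: dict[tuple[str, str], Chain] = {}
        for u in dag.predecessors(v):
            for key, chain in dp[u].items():
                if key not in cur or len(chain) > len(cur[key]):
                    cur[key] = chain
        upd: dict[tuple[str, str], Chain] = {}
        for (sstart, slast), schain in seg[comps[v]].items():
            tagged = [(schain[0][0], schain[0][1], "accessible")] + [
                (c, t, "included") for c, t in schain[1:]]
            # start fresh in this SCC
            key = (sstart, slast)
            if key not in cur or len(tagged) > len(cur.get(key, [])):
                if key not in upd or len(tagged) > len(upd[key]):
                    upd[key] = tagged
            # or extend an incoming chain whose last type alternates
            for (pstart, plast), pchain in cur.items():
                if plast == _other(sstart):
                    cand = pchain + tagged
                    key2 = (pstart, slast)
                    cur_best = max(len(cur.get(key2, [])), len(upd.get(key2, [])))
                    if len(cand) > cur_best:
                        upd[key2] = cand
        cur.update(upd)
        dp[v] = cur
        for key, chain in cur.items():
            if key not in best or len(chain) > len(best[key]):
                best[key] = chain

    def best_for(start: str) -> Chain:
        out: Chain = []
        for (s, _), chain in best.items():
            if s == start and len(chain) > len(out):
                out = chain
        return out

    alt_chain = best_for(MEANINGFUL)
    co_chain = best_for(SPURIOUS)

    omega_coeff = _branch_point_depth(dag, comps, by_scc)

    def build(chain: Chain, kind: str) -> Optional[AlternatingStructure]:
        if not chain:
            return None
        cycles = tuple(c for c, _, _ in chain)
        types = tuple(t for _, t, _ in chain)
        rels = tuple(r for _, _, r in chain[1:])
        return AlternatingStructure(kind, cycles, types, rels)

    if omega_coeff > 0:
        om = OrdinalDegree((((1, omega_coeff),)), status="lower_bound")
        return om, om, build(alt_chain or co_chain,
                             "alternating" if alt_chain else "co_alternating")
    alt = OrdinalDegree.finite(len(alt_chain))
    co = OrdinalDegree.finite(len(co_chain))
    witness = (build(alt_chain, "alternating")
               if len(alt_chain) >= len(co_chain)
               else build(co_chain, "co_alternating"))
    return alt, co, witness


def _branch_point_depth(dag: nx.DiGraph, comps, by_scc) -> int:
    """Maximal number of nested branch points along a condensation path.

    A branch point is a node from which two mutually unreachable SCCs are
    reachable, one containing a successful cycle and one a non-successful
    cycle — the structural germ of an ω-level alternating tree.
    """
    has = {}
    for i, comp in enumerate(comps):
        ts = {t for _, t in by_scc[comp]}
        has[i] = (MEANINGFUL in ts, SPURIOUS in ts)
    reach = {v: nx.descendants(dag, v) | {v} for v in dag.nodes}
    branch = set()
    for v in dag.nodes:
        succs = [u for u in reach[v] if has[u][0]]
        nons = [u for u in reach[v] if has[u][1]]
        for a in succs:
            for b in nons:
                if a != b and a not in reach[b] and b not in reach[a]:
                    branch.add(v)
                    break
            if v in branch:
                break
    if not branch:
        return 0
    sub = dag.subgraph(dag.nodes)
    depth = {}
    for v in reversed(list(nx.topological_sort(sub))):
        d = max((depth[u] for u in sub.successors(v)), default=0)
        depth[v] = d + (1 if v in branch else 0)
    return max(depth.values())


# ---------------------------------------------------------------------------
# degree case analysis (the trichotomy)

def _trichotomy(alt: OrdinalDegree, co: OrdinalDegree,
                witness) -> OrdinalDegree:
    cmp = ordinal_compare(alt, co)
    status = "lower_bound" if (alt.status != "exact" or co.status != "exact") else "exact"
    if cmp == "eq" and not alt.is_finite:
        # ω-chain (exact, non-self-dual) or a transfinite tree lower bound,
        # where self-duality is undetermined and conservatively negated
        return OrdinalDegree(alt.cnf, self_dual=False,
                             kind=witness.kind if witness else "alternating",
                             witness=witness, status=status)
    if cmp == "gt":
        return OrdinalDegree(alt.cnf, self_dual=False, kind="alternating",
                             witness=witness, status=status)
    if cmp == "lt":
        return OrdinalDegree(co.cnf, self_dual=False, kind="co_alternating",
                             witness=witness, status=status)
    return OrdinalDegree(alt.cnf, self_dual=True,
                         kind=witness.kind if witness else None,
                         witness=witness, status=status)


def rnn_degree(net, reachable_only: bool = False, cap: int = 1_000_000) -> OrdinalDegree:
    """Degree of an output-layer network in the (Büchi) hierarchy."""
    from .automata import network_to_buchi

    buchi = network_to_buchi(net, reachable_only=reachable_only)
    alt, co, witness = max_chain(buchi, cap=cap)
    return _trichotomy(alt, co, witness)


def complete_degree(net=None, assignment: Optional[TypeAssignment] = None, *,
                    muller: Optional[MullerAutomaton] = None,
                    graph: Optional[TransitionGraph] = None,
                    reachable_only: bool = True,
                    universe: str = "strongly_connected",
                    cap: int = 2_000_000) -> OrdinalDegree:
    """Degree of a freely typed network in the complete (Muller) hierarchy."""
    from .automata import network_graph

    if muller is not None:
        alt, co, witness = max_tree(muller, universe=universe, cap=cap)
    else:
        if graph is None:
            graph = network_graph(net, reachable_only=reachable_only)
        alt, co, witness = max_tree(graph=graph, assignment=assignment,
                                    universe=universe, cap=cap)
    return _trichotomy(alt, co, witness)


def buchi_segment_check(net=None, assignment: Optional[TypeAssignment] = None, *,
                        graph: Optional[TransitionGraph] = None,
                        reachable_only: bool = True,
                        universe: str = "strongly_connected",
                        cap: int = 2_000_000) -> bool:
    """Is the assignment inclusion-monotone (output-layer realisable)?

    True iff no meaningful cycle is included in a spurious one — the
    property separating the Büchi-expressible initial segment from the full
    Muller hierarchy.
    """
    from .automata import network_graph

    if graph is None:
        graph = network_graph(net, reachable_only=reachable_only)
    cycles = cycles_as_sets(graph, universe=universe, cap=cap)
    typed = [(c, assignment.type_of(c)) for c in cycles]
    for c, t in typed:
        if t != MEANINGFUL:
            continue
        for d, u in typed:
            if u == SPURIOUS and c.state_set < d.state_set:
                return False
    return True
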