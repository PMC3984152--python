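"""Synthetic networks and automata for testing and validation.

All generators are deterministic functions of an explicit integer seed (a
single ``numpy`` generator threaded through; no hidden entropy).  Planted
automata come with a construction-level guarantee of their maximal
alternating structure, re-verified at build time by an independent
brute-force search.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np

from .automata import BuchiAutomaton, MullerAutomaton
from .cycles import TransitionGraph, cycles_as_sets
from .network import BooleanNetwork
from .typing_rules import MEANINGFUL, SPURIOUS

__all__ = [
    "PlantedSpec",
    "random_network",
    "random_buchi",
    "random_muller",
    "planted_automaton",
    "brute_force_tree_lengths",
    "brute_force_chain_lengths",
]

DEFAULT_WEIGHTS = (Fraction(1, 2), Fraction(-1, 2), Fraction(1), Fraction(-1), Fraction(2))


@dataclass(frozen=True)
class PlantedSpec:
    """A requested planted structure: kind, length (int or 'omega'), seed."""

    kind: str  # alternating | co_alternating
    length: Union[int, str]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("alternating", "co_alternating"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.length != "omega" and (not isinstance(self.length, int) or self.length < 1):
            raise ValueError("length must be a positive int or 'omega'")


def random_network(n_cells: int, n_inputs: int = 1,
                   weight_set: Sequence[Fraction] = DEFAULT_WEIGHTS,
                   density: float = 0.5, seed: int = 0,
                   output_layer_size: Optional[int] = None) -> BooleanNetwork:
    """A random threshold network with rational weights.

    Each potential connection is present with probability ``density`` and
    draws its weight uniformly from ``weight_set``; backgrounds draw from
    {0, 1/2} so some cells can fire spontaneously.
    """
    rng = np.random.default_rng(seed)
    zero = Fraction(0)
    ws = list(weight_set)

    def draw() -> Fraction:
        return ws[int(rng.integers(len(ws)))] if rng.random() < density else zero

    W = tuple(tuple(draw() for _ in range(n_cells)) for _ in range(n_cells))
    U = tuple(tuple(draw() for _ in range(n_cells)) for _ in range(n_inputs))
    bg = tuple(Fraction(1, 2) if rng.random() < 0.3 else zero for _ in range(n_cells))
    names = tuple(f"c{i}" for i in range(n_cells))
    inames = tuple(f"u{k}" for k in range(n_inputs))
    out: frozenset[str] = frozenset()
    if output_layer_size:
        picks = rng.choice(n_cells, size=min(output_layer_size, n_cells), replace=False)
        out = frozenset(names[i] for i in picks)
    return BooleanNetwork(names, inames, W, U, bg, output_layer=out)


def _letters(m: int):
    return [tuple((i >> (m - 1 - k)) & 1 for k in range(m)) for i in range(1 << m)]


def random_buchi(n_states: int, alphabet_dim: int = 1, seed: int = 0) -> BuchiAutomaton:
    """A random complete deterministic Büchi automaton."""
    rng = np.random.default_rng(seed)
    letters = _letters(alphabet_dim)
    trans = {(q, a): int(rng.integers(n_states))
             for q in range(n_states) for a in letters}
    finals = {q for q in range(n_states) if rng.random() < 0.5}
    return BuchiAutomaton(range(n_states), alphabet_dim, 0, trans, finals)


def random_muller(n_states: int, alphabet_dim: int = 1, seed: int = 0) -> MullerAutomaton:
    """A random complete deterministic Muller automaton with explicit table."""
    rng = np.random.default_rng(seed)
    letters = _letters(alphabet_dim)
    trans = {(q, a): int(rng.integers(n_states))
             for q in range(n_states) for a in letters}
    graph = TransitionGraph((q, r, a) for (q, a), r in trans.items())
    cycles = cycles_as_sets(graph, universe="strongly_connected")
    table = [c.state_set for c in cycles if rng.random() < 0.5]
    return MullerAutomaton(range(n_states), alphabet_dim, 0, trans, table=table)


def planted_automaton(spec: PlantedSpec):
    """An automaton whose maximal (co-)alternating structure is known.

    Finite Büchi/Muller length k: a line of k states where state j loops
    back to 0 on letter 0 and advances on letter 1, so the cycles are
    exactly the k nested sets {0..j}; types alternate along the nesting,
    starting with the requested kind.  Length 'omega': a two-state strongly
    connected Büchi automaton whose SCC hosts both a successful and a
    non-successful cycle (a communicating opposite-type pair).

    Both a Büchi and a Muller reading are returned where applicable:
    the result is a dict with keys ``muller`` and/or ``buchi``.
    Build-time brute force re-verifies maximality.
    """
    first = MEANINGFUL if spec.kind == "alternating" else SPURIOUS
    if spec.length == "omega":
        trans = {(0, (0,)): 0, (0, (1,)): 1, (1, (0,)): 1, (1, (1,)): 0}
        buchi = BuchiAutomaton({0, 1}, 1, 0, trans, finals={0})
        alt, co = brute_force_chain_lengths(buchi)
        assert alt == "omega" and co == "omega"
        return {"buchi": buchi}

    k = spec.length
    rng = np.random.default_rng(spec.seed)
    perm = [int(x) for x in rng.permutation(k)]  # state relabelling: planted level -> name
    trans = {}
    for j in range(k):
        trans[(perm[j], (0,))] = perm[0]
        trans[(perm[j], (1,))] = perm[j + 1] if j + 1 < k else perm[0]
    nested = [frozenset(perm[: j + 1]) for j in range(k)]
    types = {nested[j]: (first if j % 2 == 0 else
                         (SPURIOUS if first == MEANINGFUL else MEANINGFUL))
             for j in range(k)}
    table = [s for s, t in types.items() if t == MEANINGFUL]
    muller = MullerAutomaton(set(perm), 1, perm[0], trans, table=table)
    alt, co = brute_force_tree_lengths(muller)
    want = (k, k - 1) if spec.kind == "alternating" else (k - 1, k)
    assert (alt, co) == want, f"planted structure not maximal: {(alt, co)} != {want}"
    return {"muller": muller}


# ---------------------------------------------------------------------------
# independent brute-force oracles (exhaustive, tiny instances only)

def _all_cycles_typed(automaton):
    graph = automaton.graph()
    cycles = cycles_as_sets(graph, universe="strongly_connected")
    if isinstance(automaton, BuchiAutomaton):
        types = {c.state_set: (MEANINGFUL if c.state_set & automaton.finals else SPURIOUS)
                 for c in cycles}
    else:
        types = {c.state_set: (MEANINGFUL if automaton.successful(c.state_set) else SPURIOUS)
                 for c in cycles}
    return graph, [c.state_set for c in cycles], types


def brute_force_tree_lengths(muller) -> tuple[int, int]:
    """Exhaustive search for the longest alternating inclusion chains.

    Tries every strictly increasing inclusion sequence of cycles with
    alternating types (extended across SCCs by one-way reachability), by
    depth-first extension — exponential, for instances of a few states.
    """
    import networkx as nx

    graph, cycles, types = _all_cycles_typed(muller)
    g = graph.as_networkx()
    comp_of = {}
    comps = list(nx.strongly_connected_components(g))
    for i, comp in enumerate(comps):
        for s in comp:
            comp_of[s] = i
    cond = nx.condensation(g, scc=comps)
    cond_reach = {v: nx.descendants(cond, v) for v in cond.nodes}

    def extendable(last: frozenset, nxt: frozenset) -> bool:
        ca, cb = comp_of[next(iter(last))], comp_of[next(iter(nxt))]
        if ca == cb:
            return last < nxt
        return cb in cond_reach[ca]

    best = {MEANINGFUL: 0, SPURIOUS: 0}

    def extend(chain: list[frozenset], start: str) -> None:
        best[start] = max(best[start], len(chain))
        last = chain[-1]
        t = types[last]
        for c in cycles:
            if c not in chain and types[c] != t and extendable(last, c):
                extend(chain + [c], start)

    for c in cycles:
        extend([c], types[c])
    return best[MEANINGFUL], best[SPURIOUS]


def brute_force_chain_lengths(buchi):
    """Exhaustive alternating-chain search for a Büchi automaton.

    Returns finite lengths, or ('omega', 'omega') when two communicating
    cycles of opposite type exist.
    """
    import networkx as nx

    graph, cycles, types = _all_cycles_typed(buchi)
    g = graph.as_networkx()
    reach = {s: nx.descendants(g, s) | {s} for s in g.nodes}

    def acc(a: frozenset, b: frozenset) -> bool:
        return any(y in reach[x] for x in a for y in b)

    for a, b in combinations(cycles, 2):
        if types[a] != types[b] and acc(a, b) and acc(b, a):
            return "omega", "omega"

    best = {MEANINGFUL: 0, SPURIOUS: 0}

    def extend(chain: list[frozenset], start: str) -> None:
        best[start] = max(best[start], len(chain))
        last = chain[-1]
        for c in cycles:
            if c in chain or types[c] == types[last]:
                continue
            if acc(last, c) and not acc(c, last):
                extend(chain + [c], start)

    for c in cycles:
        extend([c], types[c])
    return best[MEANINGFUL], best[SPURIOUS]
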