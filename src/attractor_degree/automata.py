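"""Deterministic Büchi and Muller automata over Boolean-vector alphabets.

Letters are M-bit Boolean vectors, states integers.  A deterministic Büchi
automaton accepts an infinite word iff its unique run visits a final state
infinitely often; a Muller automaton accepts iff the exact set of states
visited infinitely often belongs to its table.

The four constructions bridging threshold networks and automata live here:

* ``network_to_buchi`` / ``network_to_muller`` — the state graph of the
  automaton is the network's state space, transitions are single synchronous
  updates (exponential in the number of cells);
* ``buchi_to_network`` / ``muller_to_network`` — a threshold network whose
  cells one-hot encode letters, transitions and states of the automaton.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Optional, Sequence

from .network import (BooleanNetwork, UltimatelyPeriodicStream, decode_state,
                      step)
from .cycles import TransitionGraph

__all__ = [
    "BuchiAutomaton",
    "MullerAutomaton",
    "OmegaWord",
    "accepts",
    "network_to_buchi",
    "network_to_muller",
    "buchi_to_network",
    "muller_to_network",
    "network_graph",
    "automaton_to_json",
    "automaton_from_json",
    "automaton_to_dot",
]

Letter = tuple[int, ...]


@dataclass(frozen=True)
class OmegaWord:
    """An ultimately periodic infinite word ``prefix . period^omega``."""

    prefix: tuple[Letter, ...]
    period: tuple[Letter, ...]

    def __post_init__(self) -> None:
        if not self.period:
            raise ValueError("period must be non-empty")

    @classmethod
    def from_stream(cls, stream: UltimatelyPeriodicStream) -> "OmegaWord":
        return cls(stream.prefix, stream.period)

    def as_stream(self) -> UltimatelyPeriodicStream:
        return UltimatelyPeriodicStream(self.prefix, self.period)


class _DeterministicAutomaton:
    def __init__(self, states: Iterable[int], alphabet_dim: int, initial: int,
                 transitions: dict[tuple[int, Letter], int]):
        self.states = frozenset(states)
        self.alphabet_dim = alphabet_dim
        self.initial = initial
        self.transitions = dict(transitions)
        if initial not in self.states:
            raise ValueError("initial state not in state set")
        for (q, a), r in self.transitions.items():
            if q not in self.states or r not in self.states:
                raise ValueError(f"transition ({q},{a})->{r} uses unknown state")
            if len(a) != alphabet_dim:
                raise ValueError(f"letter {a} is not {alphabet_dim}-dimensional")

    def delta(self, q: int, a: Letter) -> Optional[int]:
        return self.transitions.get((q, a))

    def graph(self) -> TransitionGraph:
        return TransitionGraph(((q, r, a) for (q, a), r in self.transitions.items()),
                               nodes=self.states)

    def run_inf(self, word: OmegaWord) -> Optional[frozenset[int]]:
        """The inf set of the unique run, or None if a transition is missing."""
        q = self.initial
        for a in word.prefix:
            q = self.delta(q, a)
            if q is None:
                return None
        p = len(word.period)
        seen: dict[tuple[int, int], int] = {}
        trace: list[int] = [q]
        t = 0
        while True:
            key = (q, t % p)
            if key in seen:
                return frozenset(trace[seen[key]:-1] or [q])
            seen[key] = t
            q = self.delta(q, word.period[t % p])
            if q is None:
                return None
            trace.append(q)
            t += 1


class BuchiAutomaton(_DeterministicAutomaton):
    """Finite deterministic Büchi automaton (Q, Σ, q0, δ, F)."""

    def __init__(self, states, alphabet_dim, initial, transitions, finals):
        super().__init__(states, alphabet_dim, initial, transitions)
        self.finals = frozenset(finals)
        if not self.finals <= self.states:
            raise ValueError("finals must be a subset of the states")


class MullerAutomaton(_DeterministicAutomaton):
    """Finite deterministic Muller automaton (Q, Σ, q0, δ, T).

    The table may be given as an explicit collection of successful state
    sets, or lazily as a predicate over frozensets (memoised).
    """

    def __init__(self, states, alphabet_dim, initial, transitions,
                 table: Optional[Iterable[frozenset[int]]] = None,
                 table_predicate: Optional[Callable[[frozenset[int]], bool]] = None):
        super().__init__(states, alphabet_dim, initial, transitions)
        if (table is None) == (table_predicate is None):
            raise ValueError("give exactly one of table / table_predicate")
        self._explicit = None if table is None else frozenset(frozenset(s) for s in table)
        self._predicate = table_predicate
        self._memo: dict[frozenset[int], bool] = {}

    def successful(self, cycle: frozenset[int]) -> bool:
        cycle = frozenset(cycle)
        if self._explicit is not None:
            return cycle in self._explicit
        if cycle not in self._memo:
            self._memo[cycle] = bool(self._predicate(cycle))
        return self._memo[cycle]


def accepts(automaton, word: OmegaWord) -> bool:
    """ω-word acceptance for ultimately periodic words.

    An undefined transition along the run means rejection.  Büchi: the inf
    set meets the final states; Muller: the inf set is in the table.
    """
    inf = automaton.run_inf(word)
    if inf is None:
        return False
    if isinstance(automaton, BuchiAutomaton):
        return bool(inf & automaton.finals)
    return automaton.successful(inf)


def _all_letters(m: int) -> list[Letter]:
    return [tuple((i >> (m - 1 - k)) & 1 for k in range(m)) for i in range(1 << m)]


def network_graph(net: BooleanNetwork, reachable_only: bool = False) -> TransitionGraph:
    """The transition graph of a network's synchronous dynamics.

    Nodes are state codes, edges labelled by the input letter.  With
    ``reachable_only`` the graph is restricted to states reachable from the
    all-quiet initial state; unreachable states can never occur in the
    dynamics and do not affect degrees.
    """
    letters = _all_letters(net.n_inputs)
    edges = []
    if reachable_only:
        seen = {0}
        frontier = [0]
        while frontier:
            s = frontier.pop()
            for a in letters:
                t = step(net, s, a)
                edges.append((s, t, a))
                if t not in seen:
                    seen.add(t)
                    frontier.append(t)
    else:
        for s in range(1 << net.n_cells):
            for a in letters:
                edges.append((s, step(net, s, a), a))
    return TransitionGraph(edges)


def network_to_buchi(net: BooleanNetwork, reachable_only: bool = False) -> BuchiAutomaton:
    """The deterministic Büchi automaton simulating ``net``.

    States are the 2^N network states, the initial state is all-quiet, and
    the finals are the states in which at least one output cell fires: an
    ω-word is accepted iff the corresponding input stream is meaningful for
    the network under output-layer attractor typing.
    """
    if net.output_layer is None:
        raise ValueError("network_to_buchi requires a designated output layer")
    graph = network_graph(net, reachable_only)
    out_bits = net.output_bits()
    n = net.n_cells
    finals = {s for s in graph.nodes
              if any((s >> (n - 1 - b)) & 1 for b in out_bits)}
    trans = {(a, l): b for a, b, l in graph.edges}
    return BuchiAutomaton(graph.nodes, net.n_inputs, 0, trans, finals)


def network_to_muller(net: BooleanNetwork, assignment,
                      reachable_only: bool = False) -> MullerAutomaton:
    """The deterministic Muller automaton of a network with typed attractors.

    Same transition graph as :func:`network_to_buchi`; the table consists of
    exactly the meaningful attractors under ``assignment`` (evaluated
    lazily, since the number of cycles can be exponential).
    """
    from .cycles import Cycle
    from .cycles import _canonical_walk

    graph = network_graph(net, reachable_only)
    trans = {(a, l): b for a, b, l in graph.edges}

    def successful(states: frozenset[int]) -> bool:
        cyc = Cycle(states, _canonical_walk(graph, states))
        return assignment.is_meaningful(cyc)

    return MullerAutomaton(graph.nodes, net.n_inputs, 0, trans,
                           table_predicate=successful)


def _simulation_cells(automaton) -> tuple[list[str], dict[str, int]]:
    m = automaton.alphabet_dim
    letters = _all_letters(m)
    names = [f"L{''.join(map(str, a))}" for a in letters]
    names += ["delay", "latch"]
    qs = sorted(automaton.states)
    names += [f"T{q}_{''.join(map(str, a))}" for q in qs for a in letters]
    names += [f"S{q}" for q in qs]
    return names, {nm: i for i, nm in enumerate(names)}


def buchi_to_network(automaton) -> BooleanNetwork:
    """A threshold network simulating a deterministic automaton.

    Architecture (one-hot throughout): one *letter cell* per letter of the
    alphabet, firing iff the previous input equalled that letter; one
    *transition cell* per (state, letter) pair, the recurrent layer — a
    conjunction of the current one-hot state group and letter cell at
    half-weights; one read-out *state cell* per automaton state; and a
    two-cell igniter (``delay`` fires exactly once at the first step,
    ``latch`` suppresses it afterwards) that starts the run in the initial
    state.  From step 2 on, exactly one state cell fires per step, and after
    reading any finite prefix the firing state cell is the automaton state
    reached.  The output layer images the Büchi final states, so an ω-word
    is accepted iff the corresponding stream is meaningful under
    output-layer typing.
    """
    m = automaton.alphabet_dim
    letters = _all_letters(m)
    qs = sorted(automaton.states)
    names, idx = _simulation_cells(automaton)
    n = len(names)
    zero = Fraction(0)
    W = [[zero] * n for _ in range(n)]
    U = [[zero] * n for _ in range(m)]
    bg = [zero] * n

    for a in letters:
        j = idx[f"L{''.join(map(str, a))}"]
        ones = sum(a)
        if ones == 0:
            bg[j] = Fraction(1)
            for k in range(m):
                U[k][j] = Fraction(-1)
        else:
            for k in range(m):
                U[k][j] = Fraction(1, ones) if a[k] else Fraction(-1)

    bg[idx["delay"]] = Fraction(1)
    W[idx["delay"]][idx["delay"]] = Fraction(-1)
    W[idx["latch"]][idx["delay"]] = Fraction(-1)
    W[idx["delay"]][idx["latch"]] = Fraction(1)
    W[idx["latch"]][idx["latch"]] = Fraction(1)

    half = Fraction(1, 2)
    for (q, a), r in automaton.transitions.items():
        j = idx[f"T{q}_{''.join(map(str, a))}"]
        W[idx[f"L{''.join(map(str, a))}"]][j] = half
        # one-hot "current state is q": any transition cell targeting q
        for (p, b), r2 in automaton.transitions.items():
            if r2 == q:
                W[idx[f"T{p}_{''.join(map(str, b))}"]][j] = half
        if q == automaton.initial:
            W[idx["delay"]][j] = half
    for (q, a), r in automaton.transitions.items():
        W[idx[f"T{q}_{''.join(map(str, a))}"]][idx[f"S{r}"]] = Fraction(1)
    W[idx["delay"]][idx[f"S{automaton.initial}"]] = Fraction(1)

    finals = getattr(automaton, "finals", frozenset())
    output = frozenset(f"S{q}" for q in finals)
    return BooleanNetwork(
        tuple(names), tuple(f"u{k}" for k in range(m)),
        tuple(tuple(row) for row in W), tuple(tuple(row) for row in U),
        tuple(bg), comparison_mode="at_least", output_layer=output)


def state_cell_projection(net: BooleanNetwork, code: int) -> frozenset[int]:
    """Automaton states whose state cell fires in a given network state."""
    bits = decode_state(code, net.n_cells)
    return frozenset(int(nm[1:]) for nm, b in zip(net.cell_names, bits)
                     if b and nm.startswith("S"))


def muller_to_network(automaton: MullerAutomaton):
    """Simulating network plus the induced attractor typing.

    Same construction as :func:`buchi_to_network`; an attractor is declared
    meaningful iff the set of state cells spiking within it projects onto a
    member of the Muller table.
    """
    from .typing_rules import predicate_assignment

    net = buchi_to_network(automaton)

    def meaningful(cycle) -> bool:
        proj = frozenset()
        for code in cycle.state_set:
            proj |= state_cell_projection(net, code)
        return automaton.successful(proj)

    return net, predicate_assignment(meaningful, tag="muller_projection")


# ---------------------------------------------------------------------------
# serialisation

def automaton_to_json(automaton) -> str:
    d = {
        "states": sorted(automaton.states),
        "alphabet_dim": automaton.alphabet_dim,
        "initial": automaton.initial,
        "transitions": [[q, "".join(map(str, a)), r]
                        for (q, a), r in sorted(automaton.transitions.items())],
    }
    if isinstance(automaton, BuchiAutomaton):
        d["finals"] = sorted(automaton.finals)
    else:
        if automaton._explicit is None:
            raise ValueError("cannot serialise a lazy Muller table")
        d["table"] = sorted(sorted(s) for s in automaton._explicit)
    return json.dumps(d, indent=1)


def automaton_from_json(text: str):
    d = json.loads(text)
    trans = {(q, tuple(int(c) for c in a)): r for q, a, r in d["transitions"]}
    if "finals" in d:
        return BuchiAutomaton(d["states"], d["alphabet_dim"], d["initial"],
                              trans, d["finals"])
    return MullerAutomaton(d["states"], d["alphabet_dim"], d["initial"], trans,
                           table=[frozenset(s) for s in d["table"]])


def automaton_to_dot(automaton, name: str = "A") -> str:
    lines = [f"digraph {name} {{", "  rankdir=LR;"]
    finals = getattr(automaton, "finals", frozenset())
    for q in sorted(automaton.states):
        shape = "doublecircle" if q in finals else "circle"
        lines.append(f'  {q} [shape={shape}];')
    for (q, a), r in sorted(automaton.transitions.items()):
        lines.append(f'  {q} -> {r} [label="{"".join(map(str, a))}"];')
    lines.append("}")
    return "\n".join(lines)
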