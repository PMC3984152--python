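"""ω-automata: acceptance, network↔automaton constructions, serialisation."""

import pytest

from tests_helpers import all_words, zero_network

from attractor_degree.automata import (BuchiAutomaton, MullerAutomaton,
                                       OmegaWord, accepts, automaton_from_json,
                                       automaton_to_dot, automaton_to_json,
                                       buchi_to_network, muller_to_network,
                                       network_to_buchi, network_to_muller,
                                       state_cell_projection)
from attractor_degree.cycles import cycles_as_sets, sccs, scc_is_cyclic, simple_cycles
from attractor_degree.fixtures import random_buchi, random_muller, random_network
from attractor_degree.network import UltimatelyPeriodicStream, evolve, is_meaningful
from attractor_degree.typing_rules import (MEANINGFUL, output_layer_assignment,
                                           predicate_assignment)


def test_network_to_buchi_state_space():
    net = random_network(3, 1, seed=0, output_layer_size=1)
    a = network_to_buchi(net)
    assert len(a.states) == 8 and a.initial == 0
    assert len(a.transitions) == 16  # two letters per state


def test_network_without_output_layer_is_rejected():
    with pytest.raises(ValueError):
        network_to_buchi(zero_network())


def test_empty_output_layer_rejects_everything():
    net = zero_network().with_output_layer([])
    a = network_to_buchi(net)
    assert a.finals == frozenset()
    for w in all_words(1, 2):
        assert not accepts(a, w)


def test_accepts_basics():
    loop = {(0, (0,)): 0, (0, (1,)): 0}
    always = BuchiAutomaton({0}, 1, 0, loop, finals={0})
    never = BuchiAutomaton({0}, 1, 0, loop, finals=set())
    w = OmegaWord((), ((0,),))
    assert accepts(always, w) and not accepts(never, w)


def test_accepts_rejects_on_missing_transition():
    partial = BuchiAutomaton({0, 1}, 1, 0, {(0, (0,)): 0}, finals={0})
    assert accepts(partial, OmegaWord((), ((0,),)))
    assert not accepts(partial, OmegaWord((), ((1,),)))


@pytest.mark.parametrize("seed", range(5))
def test_accepts_agrees_with_long_run_simulation(seed):
    """Inf-set computed by loop detection equals the states seen in a run of
    |prefix| + 2^|Q| * |period| extra steps (the pigeonhole bound)."""
    a = random_buchi(4, 1, seed)
    for w in all_words(2, 2):
        q = a.initial
        for letter in w.prefix:
            q = a.delta(q, letter)
        horizon = (2 ** len(a.states)) * len(w.period)
        trace = []
        for t in range(2 * horizon):
            q = a.delta(q, w.period[t % len(w.period)])
            trace.append(q)
        tail = set(trace[horizon:])
        assert accepts(a, w) == bool(tail & a.finals)


@pytest.mark.parametrize("seed", range(3))
def test_network_to_buchi_matches_direct_simulation(seed):
    net = random_network(3, 1, seed=seed, output_layer_size=1)
    a = network_to_buchi(net)
    assign = output_layer_assignment(net)
    for w in all_words(3, 3):
        assert accepts(a, w) == is_meaningful(net, assign, w.as_stream())


def test_network_to_muller_graph_and_table():
    net = random_network(3, 1, seed=2)
    spurious_all = predicate_assignment(lambda c: False)
    m = network_to_muller(net, spurious_all)
    assert len(m.states) == 8
    assert not any(m.successful(c.state_set)
                   for c in cycles_as_sets(m.graph(), "strongly_connected"))
    meaningful_all = predicate_assignment(lambda c: True)
    m2 = network_to_muller(net, meaningful_all)
    for w in all_words(2, 2):
        assert accepts(m2, w)  # every run's inf set is a cycle, all successful


def test_buchi_to_network_tracks_the_run():
    """The firing state cell follows the automaton run with the start-up lag."""
    trans = {(0, (0,)): 0, (0, (1,)): 1, (1, (0,)): 0, (1, (1,)): 1}
    a = BuchiAutomaton({0, 1}, 1, 0, trans, finals={1})
    net = buchi_to_network(a)
    word = [(1,), (1,), (0,), (1,), (0,), (0,), (1,), (1,), (1,), (0,)]
    # oracle: direct automaton run
    run = [0]
    for letter in word:
        run.append(a.delta(run[-1], letter))
    stream = UltimatelyPeriodicStream(tuple(word), ((0,),))
    state = 0
    from attractor_degree.network import step
    traj = [state]
    for t in range(len(word)):
        state = step(net, state, stream.letter(t))
        traj.append(state)
    # at time t+2 the firing state cell is the state after reading word[:t]
    for t in range(len(word) - 1):
        proj = state_cell_projection(net, traj[t + 2])
        assert proj == {run[t]}, (t, proj, run[t])


def test_one_state_buchi_simulation_accepts_everything():
    a = BuchiAutomaton({0}, 1, 0, {(0, (0,)): 0, (0, (1,)): 0}, finals={0})
    net = buchi_to_network(a)
    assign = output_layer_assignment(net)
    for w in all_words(1, 2):
        assert is_meaningful(net, assign, w.as_stream())


@pytest.mark.parametrize("seed", range(3))
def test_buchi_network_language_equality(seed):
    a = random_buchi(3, 1, seed)
    net = buchi_to_network(a)
    assign = output_layer_assignment(net)
    for w in all_words(3, 3):
        assert accepts(a, w) == is_meaningful(net, assign, w.as_stream())


@pytest.mark.parametrize("seed", range(3))
def test_muller_network_language_equality(seed):
    a = random_muller(3, 1, seed)
    net, assign = muller_to_network(a)
    for w in all_words(3, 3):
        assert accepts(a, w) == is_meaningful(net, assign, w.as_stream())


def test_muller_empty_table_rejects_all():
    a = random_muller(3, 1, 0)
    empty = MullerAutomaton(a.states, 1, a.initial, a.transitions, table=[])
    net, assign = muller_to_network(empty)
    for w in all_words(1, 2):
        assert not accepts(empty, w)
        assert not is_meaningful(net, assign, w.as_stream())


@pytest.mark.parametrize("seed", range(6))
def test_buchi_monotonicity_structural_property(seed):
    """In a Büchi automaton no non-successful cycle strictly contains a
    successful one: finals are inherited upward along inclusion."""
    a = random_buchi(4, 1, seed)
    cycles = cycles_as_sets(a.graph(), "strongly_connected")
    for c in cycles:
        for d in cycles:
            if c.state_set < d.state_set and (c.state_set & a.finals):
                assert d.state_set & a.finals


def test_json_roundtrip():
    a = random_buchi(3, 2, 5)
    b = automaton_from_json(automaton_to_json(a))
    assert b.transitions == a.transitions and b.finals == a.finals
    m = random_muller(3, 1, 5)
    m2 = automaton_from_json(automaton_to_json(m))
    assert m2.transitions == m.transitions
    for c in cycles_as_sets(m.graph(), "strongly_connected"):
        assert m.successful(c.state_set) == m2.successful(c.state_set)


def test_dot_export_mentions_every_state():
    a = random_buchi(3, 1, 1)
    dot = automaton_to_dot(a)
    for q in a.states:
        assert f" {q} [" in dot
    assert "doublecircle" in dot or not a.finals
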