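"""Threshold dynamics: exactness, encoding, simulation, fixture wiring."""

import json
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from attractor_degree.cycles import Cycle, ClosedWalk
from attractor_degree.network import (BooleanNetwork, UltimatelyPeriodicStream,
                                      basal_ganglia_network, complement_network,
                                      decode_state, encode_state, evolve,
                                      is_meaningful, parse_rational,
                                      read_network, step)
from attractor_degree.typing_rules import explicit_assignment, predicate_assignment


def zero_network(n=3, m=1):
    z = Fraction(0)
    return BooleanNetwork(
        tuple(f"c{i}" for i in range(n)), tuple(f"u{k}" for k in range(m)),
        tuple(tuple(z for _ in range(n)) for _ in range(n)),
        tuple(tuple(z for _ in range(n)) for _ in range(m)),
        tuple(z for _ in range(n)))


def test_all_zero_network_is_forever_quiet():
    net = zero_network()
    assert step(net, 0b101, (1,)) == 0
    ev = evolve(net, UltimatelyPeriodicStream((), ((1,),)), initial=0b111)
    assert ev.inf_set == {0}


@pytest.mark.parametrize("source,expected", [(0, 384), (223, 511)])
def test_basal_ganglia_single_steps(source, expected, case_net):
    """Hand-checked column sums of the circuit's weight matrix under drive."""
    assert step(case_net, source, (1,)) == expected


def test_basal_ganglia_wiring():
    net = basal_ganglia_network()
    assert net.n_cells == 9 and net.n_inputs == 1
    i = net.cell_index
    assert net.cell_weights[i("STN")][i("GPi/SNr")] == 2
    assert net.cell_weights[i("Thalamus")][i("CCortex")] == 1
    assert net.cell_weights[i("GPe")][i("RTN")] == Fraction(-1, 2)
    assert net.input_weights[0][i("SC")] == 1
    assert net.input_weights[0][i("Thalamus")] == 1
    assert net.input_weights[0][i("GPi/SNr")] == 0


def test_reference_walk_simulation(case_net):
    """Driving the calibrated circuit with the realising input sequence
    visits the published 12-state closed walk and settles on its states."""
    from attractor_degree.case_study import FIG9_WALK, realize_walk_inputs

    inputs = realize_walk_inputs(case_net, FIG9_WALK)
    stream = UltimatelyPeriodicStream((), tuple((u,) for u in inputs))
    ev = evolve(case_net, stream, initial=0)
    assert tuple(ev.transient) + tuple(ev.loop)[:len(FIG9_WALK) - 1] == FIG9_WALK[:-1] \
        or tuple(ev.loop) == FIG9_WALK[:-1]
    assert ev.inf_set == {0, 384, 223, 511, 191, 63, 33, 128, 95}


def test_one_cell_self_exciting_network_latches():
    one = Fraction(1)
    net = BooleanNetwork(("c",), ("u",), ((one,),), ((one,),), (Fraction(0),))
    ev = evolve(net, UltimatelyPeriodicStream((), ((1,),)), initial=0)
    assert ev.inf_set == {1}
    # once firing, self-weight 1 sustains it even without input
    ev2 = evolve(net, UltimatelyPeriodicStream(((1,),), ((0,),)), initial=0)
    assert ev2.inf_set == {1}


@given(st.integers(1, 10), st.data())
@settings(max_examples=50, deadline=None)
def test_encode_decode_roundtrip(n, data):
    code = data.draw(st.integers(0, 2 ** n - 1))
    assert encode_state(decode_state(code, n)) == code


def test_encoding_is_msb_first():
    # quiet cells #1,#3,#4 of nine gives the published state number
    bits = [0, 1, 0, 0, 1, 1, 1, 1, 1]
    assert encode_state(bits) == 159
    assert decode_state(384, 9) == (1, 1, 0, 0, 0, 0, 0, 0, 0)


@given(st.integers(1, 7), st.sampled_from([Fraction(1, 3), Fraction(2), Fraction(7, 2)]))
@settings(max_examples=30, deadline=None)
def test_step_invariant_under_positive_rescaling(seed, scale):
    from attractor_degree.fixtures import random_network

    net = random_network(4, 1, seed=seed)
    scaled = BooleanNetwork(
        net.cell_names, net.input_names,
        tuple(tuple(w * scale for w in row) for row in net.cell_weights),
        tuple(tuple(w * scale for w in row) for row in net.input_weights),
        tuple(b * scale for b in net.background),
        tuple(t * scale for t in net.thresholds),
        net.comparison_mode, net.output_layer)
    for s in range(16):
        for u in ((0,), (1,)):
            assert step(net, s, u) == step(scaled, s, u)


def test_parse_rational_is_exact():
    assert parse_rational("1/3") == Fraction(1, 3)
    assert parse_rational("−1/2") == Fraction(-1, 2)  # unicode minus
    with pytest.raises(ValueError):
        parse_rational("0.x")


def test_read_network_roundtrip(tmp_path):
    table = tmp_path / "net.tsv"
    table.write_text("\ta\tb\na\t1/3\t-1\nb\t\t2\n")
    cfg = tmp_path / "cfg.json"
    cfg.write_text(json.dumps({
        "inputs": {"u": {"a": "1"}},
        "background": {"b": "1/2"},
        "comparison_mode": "at_least",
        "output_layer": ["b"],
    }))
    net = read_network(table, cfg)
    assert net.cell_weights[0][0] == Fraction(1, 3)
    assert net.cell_weights[1][0] == 0  # blank cell = absent edge
    assert net.background == (0, Fraction(1, 2))
    assert net.output_layer == {"b"}


def test_read_network_rejects_bad_input(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("\n")
    with pytest.raises(ValueError):
        read_network(empty)
    bad = tmp_path / "bad.tsv"
    bad.write_text("\ta\tb\na\t1\tx\nb\t\t\n")
    with pytest.raises(ValueError, match="column"):
        read_network(bad)


def test_is_meaningful_and_complement():
    one = Fraction(1)
    net = BooleanNetwork(("c",), ("u",), ((one,),), ((one,),), (Fraction(0),))
    meaningful_when_firing = predicate_assignment(lambda c: 1 in c.state_set)
    drive = UltimatelyPeriodicStream((), ((1,),))
    idle = UltimatelyPeriodicStream((), ((0,),))
    assert is_meaningful(net, meaningful_when_firing, drive)
    assert not is_meaningful(net, meaningful_when_firing, idle)
    _, flipped = complement_network(net, meaningful_when_firing)
    assert not is_meaningful(net, flipped, drive)
    assert is_meaningful(net, flipped, idle)
    _, back = complement_network(net, flipped)
    assert is_meaningful(net, back, drive)


def test_is_meaningful_raises_on_uncovered_attractor():
    net = zero_network(2)
    assignment = explicit_assignment([([1, 2], "meaningful")])
    with pytest.raises(KeyError):
        is_meaningful(net, assignment, UltimatelyPeriodicStream((), ((0,),)))
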