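"""Graph machinery: SCCs, cycle enumeration, walk decomposition, relations."""

from itertools import combinations, product

import networkx as nx
import pytest

from attractor_degree.cycles import (ClosedWalk, Cycle, TransitionGraph,
                                     accessible, attractors, closed_walks_from,
                                     communicate, constitutive_decomposition,
                                     cycles_as_sets, includes, sccs,
                                     simple_cycles)


def graph_of(pairs, nodes=None):
    return TransitionGraph(((a, b, (0,)) for a, b in pairs), nodes=nodes)


def test_single_self_loop():
    g = graph_of([(1, 1)])
    assert sccs(g) == [frozenset({1})]
    assert len(simple_cycles(g)) == 1
    assert len(closed_walks_from(g, 1)) == 1


def test_two_cycles_joined_one_way():
    # two 2-cycles joined by a one-way bridge: two ordered SCCs
    g = graph_of([(1, 2), (2, 1), (2, 3), (3, 4), (4, 3)])
    comps = sccs(g)
    assert comps == [frozenset({1, 2}), frozenset({3, 4})]
    a = simple_cycles(g, through=1)[0]
    b = simple_cycles(g, through=3)[0]
    assert accessible(a, b, g) and not accessible(b, a, g)
    assert not communicate(a, b, g)
    assert accessible(a, a, g)  # reflexive


def test_complete_3_digraph_has_5_simple_cycles():
    g = graph_of([(a, b) for a in range(3) for b in range(3) if a != b])
    assert len(simple_cycles(g)) == 5  # three 2-cycles, two 3-cycles


@pytest.mark.parametrize("n", [3, 4, 5])
def test_simple_cycles_against_subset_enumeration(n):
    """Johnson enumeration agrees with brute force over all vertex subsets:
    a set is a simple cycle iff it admits a Hamiltonian circuit of its
    induced subgraph."""
    import numpy as np

    rng = np.random.default_rng(n)
    pairs = [(a, b) for a in range(n) for b in range(n) if rng.random() < 0.5]
    g = graph_of(pairs, nodes=range(n))
    found = {c.state_set for c in simple_cycles(g)}
    eset = {(a, b) for a, b in pairs}

    brute = set()
    for k in range(1, n + 1):
        for sub in combinations(range(n), k):
            if k == 1:
                if (sub[0], sub[0]) in eset:
                    brute.add(frozenset(sub))
                continue
            from itertools import permutations
            for perm in permutations(sub[1:]):
                cyc = (sub[0],) + perm + (sub[0],)
                if all((a, b) in eset for a, b in zip(cyc, cyc[1:])):
                    brute.add(frozenset(sub))
                    break
    assert found == brute


def test_decomposition_of_published_walk():
    walk = ClosedWalk((0, 0, 384, 223, 511, 191, 63, 33, 128, 95, 33, 0))
    parts = constitutive_decomposition(walk)
    assert [p.witness.sequence for p in parts] == [
        (0, 0),
        (33, 128, 95, 33),
        (0, 384, 223, 511, 191, 63, 33, 0),
    ]
    assert all(p.is_simple() for p in parts)
    assert sum(len(p.witness) for p in parts) == len(walk)  # edge conservation


def test_decomposition_of_simple_walk_is_itself():
    walk = ClosedWalk((1, 2, 3, 1))
    parts = constitutive_decomposition(walk)
    assert len(parts) == 1 and parts[0].witness.sequence == walk.sequence


def test_decomposition_stack_trace():
    parts = constitutive_decomposition(ClosedWalk((1, 2, 3, 2, 1)))
    assert [p.witness.sequence for p in parts] == [(2, 3, 2), (1, 2, 1)]


def test_decomposition_partitions_letters():
    walk = ClosedWalk((1, 2, 1, 2, 1), letters=((0,), (1,), (1,), (0,)))
    parts = constitutive_decomposition(walk)
    assert [p.witness.letters for p in parts] == [((0,), (1,)), ((1,), (0,))]


def test_every_simple_cycle_through_root_appears_among_walks(case_graph):
    for root in (0, 127):
        walks = {w.support for w in closed_walks_from(case_graph, root,
                                                      mode="support_sets")}
        for c in simple_cycles(case_graph, through=root):
            assert c.state_set in walks


def test_cycles_live_inside_sccs(case_graph):
    comps = sccs(case_graph)
    for c in cycles_as_sets(case_graph, universe="trail_support"):
        assert any(c.state_set <= comp for comp in comps)


def test_trail_supports_are_strongly_connected_subsets(case_graph):
    trail = {c.state_set for c in cycles_as_sets(case_graph, "trail_support")}
    formal = {c.state_set for c in cycles_as_sets(case_graph, "strongly_connected")}
    assert trail < formal  # strict: closed paths may reuse transitions


def test_inclusion_relation():
    g = graph_of([(1, 2), (2, 1), (1, 1)])
    small = simple_cycles(g, through=1)[0]
    cycles = cycles_as_sets(g, universe="strongly_connected")
    big = [c for c in cycles if len(c.state_set) == 2][0]
    assert includes(small, big) and not includes(big, small)


def test_attractors_of_zero_network():
    from tests_helpers import zero_network

    assert [sorted(c.state_set) for c in attractors(zero_network(3))] == [[0]]


def test_attractors_realisable_by_streams():
    """Every enumerated attractor of a small random network is the inf set
    of a concrete ultimately periodic stream built from its witness walk."""
    import networkx as nxx

    from attractor_degree.automata import network_graph
    from attractor_degree.fixtures import random_network
    from attractor_degree.network import UltimatelyPeriodicStream, evolve

    for seed in (1, 3, 5):
        net = random_network(3, 1, seed=seed)
        graph = network_graph(net, reachable_only=True)
        for cyc in attractors(net):
            # prefix: BFS path from the initial state to the cycle
            root = cyc.witness.sequence[0]
            parent = {0: None}
            frontier = [0]
            while root not in parent:
                nxt = []
                for v in frontier:
                    for w, letter in graph.labelled_successors(v):
                        if w not in parent:
                            parent[w] = (v, letter)
                            nxt.append(w)
                frontier = nxt
            prefix = []
            v = root
            while parent[v] is not None:
                p, letter = parent[v]
                prefix.append(letter)
                v = p
            prefix.reverse()
            period = [graph.letters_between(a, b)[0]
                      for a, b in zip(cyc.witness.sequence, cyc.witness.sequence[1:])]
            ev = evolve(net, UltimatelyPeriodicStream(tuple(prefix), tuple(period)))
            assert ev.inf_set == cyc.state_set


def test_walk_cap_is_an_error():
    from attractor_degree.cycles import CycleCapExceeded

    g = graph_of([(a, b) for a in range(5) for b in range(5)])
    with pytest.raises(CycleCapExceeded):
        closed_walks_from(g, 0, cap=3)
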