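"""End-to-end analysis of the basal ganglia-thalamocortical circuit model.

The published model gives the 9-cell weight matrix and one input unit, a
reference trajectory (a closed walk through 12 states of the derived
automaton), the 16-state strongly connected component, a per-state census
of cycles and constitutive cycles, and a maximal co-alternating tree of
seven nested cycles.  It does *not* print the background-activity vector,
the threshold comparison convention, or the counting conventions behind the
census — those are calibrated here against the printed artifacts and
reported as inferred, never as published values.

Calibrated conventions (all reproduce their printed targets exactly):

* dynamics: threshold 1, fire on "sum >= threshold", background 1/2 on the
  Thalamus and 0 elsewhere (the lexicographically smallest feasible vector;
  every feasible calibration induces the same automaton);
* "# cycles from state s": the number of distinct state sets realisable as
  supports of edge-distinct closed walks rooted at s (parallel input labels
  collapsed);
* "# constitutive cycles from s": the number of distinct rooted constitutive
  cycles produced by stack-decomposing the first walk that discovers each
  support, under ascending depth-first successor order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .automata import network_graph
from .cycles import (ClosedWalk, TransitionGraph, closed_walks_from,
                     constitutive_decomposition, cycles_as_sets, sccs,
                     simple_cycles)
from .degree import MEANINGFUL, SPURIOUS, OrdinalDegree, complete_degree, max_tree
from .network import (BASAL_GANGLIA_CELLS, BASAL_GANGLIA_ROLES, BooleanNetwork,
                      basal_ganglia_network, step)
from .typing_rules import bg_assignment

__all__ = [
    "FIG9_WALK",
    "TABLE2_STATES",
    "PUBLISHED_TABLE2",
    "CalibrationResult",
    "calibrate",
    "reproduce_table2",
    "case_degree",
    "report",
]

#: the reference closed walk of the derived automaton (12 states, rooted at 0)
FIG9_WALK = (0, 0, 384, 223, 511, 191, 63, 33, 128, 95, 33, 0)

#: the published strongly connected component (= reachable set) of the automaton
TABLE2_STATES = frozenset({0, 31, 33, 63, 95, 127, 128, 159, 161, 191, 223,
                           255, 384, 417, 479, 511})

#: published per-state census: state -> (n_cycles, n_constitutive)
PUBLISHED_TABLE2 = {
    0: (68, 24), 31: (47, 20), 33: (87, 24), 63: (93, 21), 95: (39, 21),
    127: (21, 17), 128: (63, 24), 159: (77, 22), 161: (72, 20), 191: (52, 19),
    223: (43, 21), 255: (53, 17), 384: (67, 24), 417: (35, 20), 479: (48, 16),
    511: (84, 21),
}

GRID = (Fraction(0), Fraction(1, 2), Fraction(-1, 2), Fraction(1), Fraction(-1))

CYCLE_CONVENTIONS = ("support_sets", "edge_distinct_collapsed", "edge_distinct_rooted")
CONSTITUTIVE_CONVENTIONS = ("rooted_witness", "distinct_sets", "simple_through")


@dataclass
class CalibrationResult:
    """Everything the calibration decided, with its evidence.

    All values are inferred from printed artifacts, not printed themselves.
    """

    comparison_mode: str
    background: tuple[Fraction, ...]
    cycle_convention: str
    constitutive_convention: str
    walk_reproduced: bool
    scc_reproduced: bool
    table2_matches: int            # matching cells out of 32 under the chosen conventions
    convention_scores: dict        # (cycle_conv, const_conv) -> matching cells
    per_row: dict                  # state -> dict of computed vs published
    n_feasible_calibrations: int
    candidates_evaluated: int

    def network(self) -> BooleanNetwork:
        return basal_ganglia_network(background=self.background,
                                     comparison_mode=self.comparison_mode)

    def to_json(self) -> str:
        d = {
            "note": ("backgrounds, comparison mode and census conventions are "
                     "INFERRED by calibration against printed artifacts; the "
                     "source model does not print them"),
            "comparison_mode": self.comparison_mode,
            "background": {c: str(b) for c, b in
                           zip(BASAL_GANGLIA_CELLS, self.background)},
            "cycle_convention": self.cycle_convention,
            "constitutive_convention": self.constitutive_convention,
            "walk_reproduced": self.walk_reproduced,
            "scc_reproduced": self.scc_reproduced,
            "table2_matching_cells": self.table2_matches,
            "convention_scores": {f"{a}+{b}": v for (a, b), v in
                                  self.convention_scores.items()},
            "per_row": self.per_row,
            "n_feasible_calibrations": self.n_feasible_calibrations,
            "candidates_evaluated": self.candidates_evaluated,
        }
        return json.dumps(d, indent=1)


def _walk_feasible(net: BooleanNetwork, walk: Sequence[int]) -> bool:
    return all(any(step(net, a, (u,)) == b for u in (0, 1))
               for a, b in zip(walk, walk[1:]))


def realize_walk_inputs(net: BooleanNetwork, walk: Sequence[int]) -> list[int]:
    """An input bit per transition realising the walk (first choice wins)."""
    out = []
    for a, b in zip(walk, walk[1:]):
        for u in (0, 1):
            if step(net, a, (u,)) == b:
                out.append(u)
                break
        else:
            raise ValueError(f"transition {a}->{b} not realisable")
    return out


def _feasible_backgrounds(mode: str) -> tuple[list[tuple[Fraction, ...]], int]:
    """Grid search pruned cell-by-cell against the reference-walk transitions."""
    base = basal_ganglia_network()
    n = base.n_cells
    W = base.cell_weights
    trans = list(zip(FIG9_WALK, FIG9_WALK[1:]))
    strict = mode == "strictly_greater"

    def fires(s: Fraction) -> bool:
        return s > 1 if strict else s >= 1

    def cellsum(j: int, state: int, u: int) -> Fraction:
        s = sum((W[i][j] for i in range(n) if (state >> (n - 1 - i)) & 1),
                Fraction(0))
        if u and j < 2:  # the input unit projects to SC and Thalamus
            s += 1
        return s

    checked = 0
    per_cell: list[list[Fraction]] = []
    for j in range(2, n):
        ok = []
        for bg in GRID:
            checked += 1
            if all(fires(cellsum(j, a, 0) + bg) == bool((b >> (n - 1 - j)) & 1)
                   for a, b in trans):
                ok.append(bg)
        per_cell.append(ok)
    pairs = []
    for bgS, bgT in product(GRID, GRID):
        checked += 1
        good = True
        for a, b in trans:
            wS, wT = bool((b >> (n - 1)) & 1), bool((b >> (n - 2)) & 1)
            if not any(fires(cellsum(0, a, u) + bgS) == wS and
                       fires(cellsum(1, a, u) + bgT) == wT for u in (0, 1)):
                good = False
                break
        if good:
            pairs.append((bgS, bgT))
    out = [(bgS, bgT) + rest
           for (bgS, bgT) in pairs for rest in product(*per_cell)]
    return out, checked


def _census(graph: TransitionGraph, states: Sequence[int],
            cycle_conv: str, const_conv: str) -> dict[int, tuple[int, int]]:
    res = {}
    for s in sorted(states):
        if cycle_conv == "support_sets":
            walks = closed_walks_from(graph, s, mode="support_sets")
            n_cycles = len(walks)
        elif cycle_conv == "edge_distinct_collapsed":
            walks = closed_walks_from(graph, s, mode="edge_distinct_collapsed")
            n_cycles = len(walks)
        else:
            walks = closed_walks_from(graph, s, mode="edge_distinct_rooted")
            n_cycles = len(walks)
        if const_conv == "rooted_witness":
            wits = (walks if cycle_conv == "support_sets"
                    else closed_walks_from(graph, s, mode="support_sets"))
            seen = set()
            for w in wits:
                for c in constitutive_decomposition(w):
                    seen.add(c.witness.sequence)
            n_const = len(seen)
        elif const_conv == "distinct_sets":
            wits = closed_walks_from(graph, s, mode="support_sets")
            seen = set()
            for w in wits:
                for c in constitutive_decomposition(w):
                    seen.add(c.state_set)
            n_const = len(seen)
        else:  # simple_through
            n_const = len(simple_cycles(graph, through=s))
        res[s] = (n_cycles, n_const)
    return res


def calibrate(verify_table2: bool = True) -> CalibrationResult:
    """Search dynamics conventions and census conventions against the
    printed artifacts.

    The background grid {0, ±1/2, ±1} per cell and both threshold
    comparisons are pruned against the reference walk, then filtered on
    reproducing the published 16-state component; ties break to the
    lexicographically smallest background with 'at_least' preferred.  Census
    conventions are then scored by matching cells of the published census.
    """
    feasible = []
    evaluated = 0
    for mode in ("at_least", "strictly_greater"):
        bgs, checked = _feasible_backgrounds(mode)
        evaluated += checked
        for bg in bgs:
            net = basal_ganglia_network(background=bg, comparison_mode=mode)
            if not _walk_feasible(net, FIG9_WALK):
                continue
            graph = network_graph(net, reachable_only=True)
            if frozenset(graph.nodes) != TABLE2_STATES:
                continue
            comps = [c for c in sccs(graph) if 0 in c]
            if comps[0] != TABLE2_STATES:
                continue
            feasible.append((mode, bg))
    if not feasible:
        raise RuntimeError(
            "no grid calibration reproduces both the reference walk and the "
            "published strongly connected component — report this, do not patch it")
    feasible.sort(key=lambda mb: (mb[0] != "at_least", mb[1]))
    mode, bg = feasible[0]
    net = basal_ganglia_network(background=bg, comparison_mode=mode)
    graph = network_graph(net, reachable_only=True)

    scores = {}
    censuses = {}
    if verify_table2:
        for cc, kc in product(CYCLE_CONVENTIONS, CONSTITUTIVE_CONVENTIONS):
            census = _census(graph, sorted(TABLE2_STATES), cc, kc)
            censuses[(cc, kc)] = census
            scores[(cc, kc)] = sum(
                (census[s][0] == PUBLISHED_TABLE2[s][0]) +
                (census[s][1] == PUBLISHED_TABLE2[s][1])
                for s in PUBLISHED_TABLE2)
        (cc, kc) = max(scores, key=lambda k: (scores[k],
                                              -CYCLE_CONVENTIONS.index(k[0]),
                                              -CONSTITUTIVE_CONVENTIONS.index(k[1])))
        census = censuses[(cc, kc)]
        per_row = {s: {"computed_cycles": census[s][0],
                       "published_cycles": PUBLISHED_TABLE2[s][0],
                       "computed_constitutive": census[s][1],
                       "published_constitutive": PUBLISHED_TABLE2[s][1]}
                   for s in sorted(PUBLISHED_TABLE2)}
        best = scores[(cc, kc)]
    else:
        cc, kc = "support_sets", "rooted_witness"
        per_row, best = {}, 0

    return CalibrationResult(
        comparison_mode=mode, background=bg,
        cycle_convention=cc, constitutive_convention=kc,
        walk_reproduced=True, scc_reproduced=True,
        table2_matches=best, convention_scores=scores, per_row=per_row,
        n_feasible_calibrations=len(feasible), candidates_evaluated=evaluated)


def reproduce_table2(calibrated: CalibrationResult) -> pd.DataFrame:
    """The per-state cycle census under the calibrated conventions."""
    graph = network_graph(calibrated.network(), reachable_only=True)
    census = _census(graph, sorted(TABLE2_STATES),
                     calibrated.cycle_convention,
                     calibrated.constitutive_convention)
    return pd.DataFrame(
        [(s, c, k) for s, (c, k) in sorted(census.items())],
        columns=["state", "n_cycles", "n_constitutive"])


def case_degree(calibrated: CalibrationResult):
    """Type every census cycle with the neurobiological rule and compute the
    complete-hierarchy degree.

    Returns ``(degree, details)``: the degree carries the witness chain;
    details include all maximal co-alternating trees (as state-set chains),
    and the check that no alternating tree attains the maximal length.
    """
    graph = network_graph(calibrated.network(), reachable_only=True)
    assign = bg_assignment(BASAL_GANGLIA_ROLES)
    degree = complete_degree(graph=graph, assignment=assign,
                             universe="trail_support")

    cycles = cycles_as_sets(graph, universe="trail_support")
    types = {c.state_set: assign.type_of(c) for c in cycles}
    ordered = sorted(types, key=lambda s: (len(s), sorted(s)))
    dp: dict[tuple[frozenset, str], int] = {}
    count: dict[tuple[frozenset, str], int] = {}
    for c in ordered:
        t = types[c]
        for start in (MEANINGFUL, SPURIOUS):
            bestv, cnt = 0, 0
            for d in ordered:
                if len(d) >= len(c):
                    break
                if d < c and types[d] != t:
                    v = dp.get((d, start), 0)
                    if v > bestv:
                        bestv, cnt = v, count[(d, start)]
                    elif v == bestv and v > 0:
                        cnt += count[(d, start)]
            if bestv > 0:
                dp[(c, start)] = bestv + 1
                count[(c, start)] = cnt
            elif t == start:
                dp[(c, start)] = 1
                count[(c, start)] = 1
    co_max = max((v for (c, s), v in dp.items() if s == SPURIOUS), default=0)
    alt_max = max((v for (c, s), v in dp.items() if s == MEANINGFUL), default=0)
    n_max_trees = sum(cnt for (c, s), cnt in count.items()
                      if s == SPURIOUS and dp[(c, s)] == co_max)

    witness_rows = []
    if degree.witness is not None:
        for cyc, t in zip(degree.witness.cycles, degree.witness.types):
            seq = cyc.witness.sequence
            witness_rows.append({"states": sorted(cyc.state_set),
                                 "witness_walk": list(seq),
                                 "type": t})
    details = {
        "n_cycles_typed": len(cycles),
        "max_co_alternating": co_max,
        "max_alternating": alt_max,
        "n_maximal_co_alternating_trees": n_max_trees,
        "no_alternating_tree_of_maximal_length": alt_max < co_max,
        "witness_chain": witness_rows,
    }
    return degree, details


def report(out_dir, calibrated: Optional[CalibrationResult] = None) -> list[Path]:
    """Write the full case-study report (deterministic, rerun-identical).

    Files: calibration.json, table2.csv, degree.json, automaton.dot,
    scc.dot and summary.txt.
    """
    from .automata import automaton_to_dot, network_to_muller

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if calibrated is None:
        calibrated = calibrate()
    net = calibrated.network()
    graph = network_graph(net, reachable_only=False)
    scc_graph = network_graph(net, reachable_only=True)

    files = []

    p = out / "calibration.json"
    p.write_text(calibrated.to_json())
    files.append(p)

    table2 = reproduce_table2(calibrated)
    p = out / "table2.csv"
    table2.to_csv(p, index=False)
    files.append(p)

    degree, details = case_degree(calibrated)
    p = out / "degree.json"
    p.write_text(json.dumps({
        "degree_cnf": list(degree.cnf),
        "degree_pretty": degree.pretty(),
        "kind": degree.kind,
        "self_dual": degree.self_dual,
        "status": degree.status,
        **details,
    }, indent=1))
    files.append(p)

    def dot(g: TransitionGraph, name: str) -> str:
        lines = [f"digraph {name} {{", "  rankdir=LR;"]
        for v in g.nodes:
            lines.append(f"  {v} [shape=circle];")
        for a, b, l in g.edges:
            lines.append(f'  {a} -> {b} [label="{"".join(map(str, l))}"];')
        lines.append("}")
        return "\n".join(lines)

    p = out / "automaton.dot"
    p.write_text(dot(graph, "automaton"))
    files.append(p)
    p = out / "scc.dot"
    p.write_text(dot(scc_graph, "scc"))
    files.append(p)

    inputs = realize_walk_inputs(net, FIG9_WALK)
    summary = [
        "Basal ganglia-thalamocortical case study",
        "========================================",
        "",
        "Calibrated dynamics (INFERRED, not printed in the source model):",
        f"  comparison mode : {calibrated.comparison_mode}",
        "  background      : " + ", ".join(
            f"{c}={b}" for c, b in zip(BASAL_GANGLIA_CELLS, calibrated.background)),
        f"  census conventions: cycles={calibrated.cycle_convention}, "
        f"constitutive={calibrated.constitutive_convention}",
        "",
        f"Reference walk reproduced: {calibrated.walk_reproduced} "
        f"(inputs {''.join(map(str, inputs))})",
        f"Strongly connected component reproduced: {calibrated.scc_reproduced} "
        f"({len(TABLE2_STATES)} states)",
        f"Census agreement: {calibrated.table2_matches}/32 cells",
        "",
        f"Attractor-based degree: {degree.pretty()} "
        f"({degree.kind}, {'self-dual' if degree.self_dual else 'non-self-dual'})",
        f"  maximal co-alternating tree length: {details['max_co_alternating']}",
        f"  maximal alternating tree length:    {details['max_alternating']}",
        f"  number of maximal co-alternating trees: "
        f"{details['n_maximal_co_alternating_trees']}",
        "",
        "Witness chain (innermost first):",
    ]
    for row in details["witness_chain"]:
        summary.append(f"  {row['type']:11s} {row['states']}")
    p = out / "summary.txt"
    p.write_text("\n".join(summary) + "\n")
    files.append(p)
    return files
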