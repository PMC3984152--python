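"""Meaningful/spurious type assignments for attractors and cycles.

Three sources of typings:

* *output-layer* semantics — a cycle is meaningful iff some designated
  output cell fires somewhere inside it (the restriction that pins networks
  to deterministic-Büchi expressive power, and the only inclusion-monotone
  family);
* arbitrary user *predicates* or *explicit lists* (the fully general Muller
  setting);
* the basal-ganglia *neurobiological rule*, which types vertex-simple
  cycles from the activity of SC, Thalamus and GPi/SNr along one traversal
  and extends to composite closed walks by majority vote over the
  constitutive decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

from .cycles import ClosedWalk, Cycle, constitutive_decomposition
from .network import BooleanNetwork

__all__ = [
    "MEANINGFUL",
    "SPURIOUS",
    "TypeAssignment",
    "output_layer_assignment",
    "predicate_assignment",
    "explicit_assignment",
    "bg_constitutive_type",
    "bg_cycle_type",
    "bg_assignment",
]

MEANINGFUL = "meaningful"
SPURIOUS = "spurious"


class UncoveredCycleError(KeyError):
    """An explicit assignment was queried on a cycle it does not cover."""


@dataclass(frozen=True)
class TypeAssignment:
    """A total meaningful/spurious labelling of cycles.

    ``classify`` maps a :class:`Cycle` to ``"meaningful"`` or
    ``"spurious"``; equal state sets (with equal witnesses where the rule is
    walk-sensitive) receive equal types.  ``provenance`` records how the
    assignment was produced.
    """

    classify: Callable[[Cycle], str]
    provenance: str

    def type_of(self, cycle: Cycle) -> str:
        t = self.classify(cycle)
        if t not in (MEANINGFUL, SPURIOUS):
            raise ValueError(f"classifier returned {t!r}")
        return t

    def is_meaningful(self, cycle: Cycle) -> bool:
        return self.type_of(cycle) == MEANINGFUL

    def complement(self) -> "TypeAssignment":
        """Flip every classification and nothing else (an involution)."""
        inner = self.classify
        return TypeAssignment(
            lambda c: MEANINGFUL if inner(c) == SPURIOUS else SPURIOUS,
            provenance=f"complement({self.provenance})")


def output_layer_assignment(net: BooleanNetwork) -> TypeAssignment:
    """Meaningful iff some output cell fires in some state of the cycle.

    Inclusion-monotone by construction: a supercycle visits every state of
    its subcycles, so no meaningful cycle can sit inside a spurious one.
    """
    if net.output_layer is None:
        raise ValueError("network has no output layer")
    bits = net.output_bits()
    n = net.n_cells

    def classify(cycle: Cycle) -> str:
        for s in cycle.state_set:
            if any((s >> (n - 1 - b)) & 1 for b in bits):
                return MEANINGFUL
        return SPURIOUS

    return TypeAssignment(classify, provenance="output_layer")


def predicate_assignment(predicate: Callable[[Cycle], bool],
                         tag: str = "predicate") -> TypeAssignment:
    """Wrap an arbitrary boolean predicate (True = meaningful)."""
    return TypeAssignment(
        lambda c: MEANINGFUL if predicate(c) else SPURIOUS, provenance=tag)


def explicit_assignment(entries: Iterable[tuple[Iterable[int], str]]) -> TypeAssignment:
    """An explicit list of (state set, type) pairs; unknown cycles raise."""
    table = {frozenset(states): t for states, t in entries}
    for t in table.values():
        if t not in (MEANINGFUL, SPURIOUS):
            raise ValueError(f"bad type {t!r}")

    def classify(cycle: Cycle) -> str:
        try:
            return table[cycle.state_set]
        except KeyError:
            raise UncoveredCycleError(
                f"cycle {sorted(cycle.state_set)} not covered by the explicit list")

    return TypeAssignment(classify, provenance="explicit_list")


def bg_constitutive_type(walk: ClosedWalk, roles: Mapping[str, int],
                         n_cells: int = 9) -> str:
    """Neurobiological typing of one vertex-simple (constitutive) cycle.

    Spurious iff, over one traversal (endpoint counted once), either
    (a) some state has SC active with the Thalamus quiet, or
    (b) GPi/SNr is quiet during at least half of the duration.
    Meaningful otherwise.  The half-duration reading of the output-nuclei
    criterion is fixed by the published type labels of the even-length
    cycles (a strict majority would flip them).
    """
    if not walk.is_vertex_simple():
        raise ValueError("constitutive typing requires a vertex-simple walk")
    for key in ("SC", "Thalamus", "GPi/SNr"):
        if key not in roles:
            raise ValueError(f"missing role bit for {key}")
    sc, th, gpi = roles["SC"], roles["Thalamus"], roles["GPi/SNr"]

    def bit(code: int, i: int) -> int:
        return (code >> (n_cells - 1 - i)) & 1

    states = walk.period_states
    if any(bit(s, sc) and not bit(s, th) for s in states):
        return SPURIOUS
    quiet = sum(1 for s in states if not bit(s, gpi))
    return SPURIOUS if 2 * quiet >= len(states) else MEANINGFUL


def bg_cycle_type(walk: ClosedWalk, roles: Mapping[str, int],
                  n_cells: int = 9) -> str:
    """Neurobiological typing of an arbitrary closed walk.

    Decompose into constitutive cycles and take the majority type; an exact
    tie is meaningful.  Vertex-simple walks reduce to
    :func:`bg_constitutive_type`.
    """
    parts = constitutive_decomposition(walk)
    votes = [bg_constitutive_type(p.witness, roles, n_cells) for p in parts]
    m = votes.count(MEANINGFUL)
    return MEANINGFUL if 2 * m >= len(votes) else SPURIOUS


def bg_assignment(roles: Mapping[str, int], n_cells: int = 9) -> TypeAssignment:
    """The case-study rule as a TypeAssignment over cycles.

    The rule is walk-sensitive, so the cycle's witness walk is used; for
    constitutive cycles the witness is vertex-simple and the result depends
    only on the state set.
    """
    return TypeAssignment(
        lambda c: bg_cycle_type(c.witness, roles, n_cells),
        provenance="bg_rule")
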