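"""Boolean recurrent neural networks with exact threshold dynamics.

A first-order Boolean recurrent neural network is a finite set of
McCulloch-Pitts threshold units wired by rational synaptic weights, driven
synchronously by a stream of Boolean input vectors.  A cell fires at time
``t+1`` whenever the rational sum of its afferent activity at time ``t``
(recurrent input, external input and background activity) reaches its
threshold.  All arithmetic is exact (:class:`fractions.Fraction`); dynamics
are therefore bit-reproducible and invariant under a common positive
rescaling of weights, backgrounds and thresholds.

States are identified with integers: cell #1 is the most significant bit,
so the 9-cell state in which only the first two cells fire is ``0b110000000
= 384``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "BooleanNetwork",
    "UltimatelyPeriodicStream",
    "Evolution",
    "step",
    "evolve",
    "is_meaningful",
    "read_network",
    "basal_ganglia_network",
    "complement_network",
    "encode_state",
    "decode_state",
    "BASAL_GANGLIA_CELLS",
]

# unicode minus shows up in published tables
_MINUS = re.compile(r"[−–]")


def parse_rational(token: str) -> Fraction:
    """Parse a rational literal such as ``1``, ``-1/2`` or ``−1/2`` exactly."""
    token = _MINUS.sub("-", token.strip())
    if not token:
        return Fraction(0)
    try:
        return Fraction(token)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"not a rational literal: {token!r}") from exc


def encode_state(bits: Sequence[int]) -> int:
    """Encode a Boolean cell vector as an integer, cell #1 = most significant bit."""
    code = 0
    for b in bits:
        code = (code << 1) | (1 if b else 0)
    return code


def decode_state(code: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state` for an ``n``-cell network."""
    if not 0 <= code < (1 << n):
        raise ValueError(f"state code {code} out of range for {n} cells")
    return tuple((code >> (n - 1 - i)) & 1 for i in range(n))


@dataclass(frozen=True)
class BooleanNetwork:
    """A first-order Boolean recurrent neural network.

    Parameters
    ----------
    cell_names :
        Ordered activation-cell identifiers (N cells).
    input_names :
        Ordered input-unit identifiers (M units).
    cell_weights :
        N x N matrix of exact rationals; ``cell_weights[i][j]`` is the weight
        of the connection from cell ``i`` to cell ``j``.
    input_weights :
        M x N matrix; ``input_weights[k][j]`` is the weight from input unit
        ``k`` to cell ``j``.
    background :
        Per-cell background activity (length N).
    thresholds :
        Per-cell firing threshold, 1 by default.
    comparison_mode :
        ``"at_least"`` (fire when the sum reaches the threshold) or
        ``"strictly_greater"``.
    output_layer :
        Designated subset of cells (``None`` when the network has no output
        layer; an empty frozenset is a designated-but-empty layer).  An
        attractor is meaningful under output-layer semantics when some
        output cell fires inside it.
    """

    cell_names: tuple[str, ...]
    input_names: tuple[str, ...]
    cell_weights: tuple[tuple[Fraction, ...], ...]
    input_weights: tuple[tuple[Fraction, ...], ...]
    background: tuple[Fraction, ...]
    thresholds: tuple[Fraction, ...] = None  # type: ignore[assignment]
    comparison_mode: str = "at_least"
    output_layer: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        n, m = len(self.cell_names), len(self.input_names)
        if self.thresholds is None:
            object.__setattr__(self, "thresholds", tuple(Fraction(1) for _ in range(n)))
        if len(self.cell_weights) != n or any(len(row) != n for row in self.cell_weights):
            raise ValueError(f"cell_weights must be {n}x{n}")
        if len(self.input_weights) != m or any(len(row) != n for row in self.input_weights):
            raise ValueError(f"input_weights must be {m}x{n}")
        if len(self.background) != n or len(self.thresholds) != n:
            raise ValueError("background/thresholds length must equal the cell count")
        if self.comparison_mode not in ("at_least", "strictly_greater"):
            raise ValueError(f"unknown comparison_mode {self.comparison_mode!r}")
        if self.output_layer is not None and not self.output_layer <= set(self.cell_names):
            raise ValueError("output_layer must be a subset of the cells")

    @property
    def n_cells(self) -> int:
        return len(self.cell_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    def cell_index(self, name: str) -> int:
        return self.cell_names.index(name)

    def output_bits(self) -> tuple[int, ...]:
        """Bit positions (0 = MSB) of the output-layer cells."""
        return tuple(sorted(self.cell_names.index(c) for c in self.output_layer or ()))

    def with_output_layer(self, cells: Iterable[str]) -> "BooleanNetwork":
        return BooleanNetwork(
            self.cell_names, self.input_names, self.cell_weights, self.input_weights,
            self.background, self.thresholds, self.comparison_mode, frozenset(cells),
        )


@dataclass(frozen=True)
class UltimatelyPeriodicStream:
    """The input stream ``prefix . period^omega`` of Boolean input vectors."""

    prefix: tuple[tuple[int, ...], ...]
    period: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.period) == 0:
            raise ValueError("period must be non-empty")

    @classmethod
    def from_bitstrings(cls, prefix: Sequence[str], period: Sequence[str]) -> "UltimatelyPeriodicStream":
        conv = lambda s: tuple(int(c) for c in s)
        return cls(tuple(conv(s) for s in prefix), tuple(conv(s) for s in period))

    def letter(self, t: int) -> tuple[int, ...]:
        if t < len(self.prefix):
            return self.prefix[t]
        return self.period[(t - len(self.prefix)) % len(self.period)]


@dataclass(frozen=True)
class Evolution:
    """A fully resolved evolution: transient, detected loop, and its inf set."""

    transient: tuple[int, ...]
    loop: tuple[int, ...]
    inf_set: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.loop:
            raise ValueError("loop must be non-empty")
        object.__setattr__(self, "inf_set", frozenset(self.loop))


def step(net: BooleanNetwork, state: int, letter: tuple[int, ...]) -> int:
    """One synchronous update of every cell; exact rational threshold test."""
    if len(letter) != net.n_inputs:
        raise ValueError(f"input has {len(letter)} bits, expected {net.n_inputs}")
    n = net.n_cells
    bits = decode_state(state, n)
    out = 0
    strict = net.comparison_mode == "strictly_greater"
    for j in range(n):
        s = net.background[j]
        for i in range(n):
            if bits[i]:
                s += net.cell_weights[i][j]
        for k in range(net.n_inputs):
            if letter[k]:
                s += net.input_weights[k][j]
        fired = s > net.thresholds[j] if strict else s >= net.thresholds[j]
        out = (out << 1) | (1 if fired else 0)
    return out


def evolve(net: BooleanNetwork, stream: UltimatelyPeriodicStream, initial: int = 0) -> Evolution:
    """Run the network until a (state, period-phase) pair repeats.

    Termination is guaranteed by pigeonhole within ``2^N * |period|`` steps
    past the prefix; the states on the detected loop are exactly the states
    visited infinitely often.
    """
    p = len(stream.period)
    states = [initial]
    state = initial
    t = 0
    seen: dict[tuple[int, int], int] = {}
    while True:
        if t >= len(stream.prefix):
            key = (state, (t - len(stream.prefix)) % p)
            if key in seen:
                start = seen[key]
                return Evolution(tuple(states[:start]), tuple(states[start:-1]))
            seen[key] = t
        state = step(net, state, stream.letter(t))
        states.append(state)
        t += 1


def is_meaningful(net: BooleanNetwork, assignment, stream: UltimatelyPeriodicStream,
                  initial: int = 0) -> bool:
    """Membership of ``stream`` in the neural language of ``net``.

    The induced attractor (the inf set of the evolution) is typed by
    ``assignment``; an uncovered attractor raises rather than defaulting.
    """
    from .cycles import Cycle, ClosedWalk

    ev = evolve(net, stream, initial)
    walk = ClosedWalk(tuple(ev.loop) + (ev.loop[0],))
    return assignment.is_meaningful(Cycle(frozenset(ev.inf_set), walk))


def _parse_matrix(table_path: Path) -> tuple[tuple[str, ...], dict[tuple[str, str], Fraction]]:
    text = Path(table_path).read_text()
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    if len(rows) < 2:
        raise ValueError(f"{table_path}: empty adjacency matrix")
    targets = [c.strip() for c in rows[0][1:] if c.strip()]
    weights: dict[tuple[str, str], Fraction] = {}
    sources = []
    for r, row in enumerate(rows[1:], start=2):
        src = row[0].strip()
        if not src:
            raise ValueError(f"{table_path}:{r}: missing source name")
        sources.append(src)
        for c, tok in enumerate(row[1:]):
            if c >= len(targets):
                if tok.strip():
                    raise ValueError(f"{table_path}:{r}: value beyond header columns")
                continue
            if tok.strip():
                try:
                    w = parse_rational(tok)
                except ValueError as exc:
                    raise ValueError(f"{table_path}:{r} column {targets[c]!r}: {exc}") from exc
                if w != 0:
                    weights[(src, targets[c])] = w
    if set(sources) != set(targets):
        raise ValueError(
            f"{table_path}: source names {sources} do not match target names {targets}")
    return tuple(sources), weights


def read_network(table_path, config_path=None) -> BooleanNetwork:
    """Read a network from a TSV adjacency matrix plus a JSON config.

    The TSV follows the published-table orientation: rows are sources,
    columns targets, entries rational literals, blanks absent edges.  The
    JSON config supplies input wiring, backgrounds, thresholds, comparison
    mode and the output layer (all optional; rationals given as strings).
    """
    cells, weights = _parse_matrix(Path(table_path))
    cfg = json.loads(Path(config_path).read_text()) if config_path else {}
    zero = Fraction(0)

    def lookup(d: dict, name: str, default: Fraction) -> Fraction:
        v = d.get(name)
        return parse_rational(str(v)) if v is not None else default

    inputs = cfg.get("inputs", {})
    for unit, wiring in inputs.items():
        for tgt in wiring:
            if tgt not in cells:
                raise ValueError(f"input unit {unit!r} targets unknown cell {tgt!r}")
    for key in ("background", "thresholds"):
        for name in cfg.get(key, {}):
            if name not in cells:
                raise ValueError(f"{key} entry for unknown cell {name!r}")
    input_names = tuple(inputs)
    cell_w = tuple(tuple(weights.get((s, t), zero) for t in cells) for s in cells)
    input_w = tuple(
        tuple(lookup(inputs[u], t, zero) for t in cells) for u in input_names)
    bg = tuple(lookup(cfg.get("background", {}), c, zero) for c in cells)
    th = tuple(lookup(cfg.get("thresholds", {}), c, Fraction(1)) for c in cells)
    return BooleanNetwork(
        cells, input_names, cell_w, input_w, bg, th,
        cfg.get("comparison_mode", "at_least"),
        frozenset(cfg.get("output_layer", [])),
    )


BASAL_GANGLIA_CELLS = (
    "SC", "Thalamus", "RTN", "GPi/SNr", "STN", "GPe", "Str-D2", "Str-D1", "CCortex")

#: bit positions (0 = MSB) of the cells entering the neurobiological typing rule
BASAL_GANGLIA_ROLES = {"SC": 0, "Thalamus": 1, "GPi/SNr": 3}


def basal_ganglia_network(
    background: Sequence[Fraction] | None = None,
    comparison_mode: str = "at_least",
    output_layer: Iterable[str] = (),
) -> BooleanNetwork:
    """The 9-cell basal ganglia-thalamocortical circuit.

    Cells in published-table order (SC, Thalamus, RTN, GPi/SNr, STN, GPe,
    Str-D2, Str-D1, CCortex) with a single sensory input unit projecting to
    SC and Thalamus with weight 1.  The background vector is a calibration
    parameter (the published table prints none); see
    :func:`attractor_degree.case_study.calibrate`.
    """
    from importlib.resources import files

    table = files("attractor_degree.data").joinpath("basal_ganglia.tsv")
    cells, weights = _parse_matrix(table)  # type: ignore[arg-type]
    assert cells == BASAL_GANGLIA_CELLS
    zero = Fraction(0)
    cell_w = tuple(tuple(weights.get((s, t), zero) for t in cells) for s in cells)
    input_w = (tuple(Fraction(1) if t in ("SC", "Thalamus") else zero for t in cells),)
    bg = tuple(background) if background is not None else tuple(zero for _ in cells)
    return BooleanNetwork(cells, ("IN",), cell_w, input_w, bg,
                          comparison_mode=comparison_mode,
                          output_layer=frozenset(output_layer))


def complement_network(net: BooleanNetwork, assignment):
    """Same network, every attractor type flipped (an involution)."""
    return net, assignment.complement()
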