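"""Shared helpers for the test suite."""

from fractions import Fraction
from itertools import product

from attractor_degree.automata import OmegaWord
from attractor_degree.network import BooleanNetwork


def zero_network(n=3, m=1):
    z = Fraction(0)
    return BooleanNetwork(
        tuple(f"c{i}" for i in range(n)), tuple(f"u{k}" for k in range(m)),
        tuple(tuple(z for _ in range(n)) for _ in range(n)),
        tuple(tuple(z for _ in range(n)) for _ in range(m)),
        tuple(z for _ in range(n)))


def all_words(max_prefix: int, max_period: int, m: int = 1):
    """Every ultimately periodic word u.v^ω with |u| <= max_prefix,
    1 <= |v| <= max_period over the 2^m-letter alphabet."""
    letters = [tuple((i >> (m - 1 - k)) & 1 for k in range(m))
               for i in range(1 << m)]
    out = []
    for lu in range(max_prefix + 1):
        for u in product(letters, repeat=lu):
            for lv in range(1, max_period + 1):
                for v in product(letters, repeat=lv):
                    out.append(OmegaWord(tuple(u), tuple(v)))
    return out
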