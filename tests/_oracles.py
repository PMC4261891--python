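"""Independent brute-force reference implementations for the entropy core.

Deliberately written in plain Python, position by position, without numpy
and without importing the package's own operators, so they constitute an
independent oracle for the partial-sum / local-frequency entropy math.
"""
import math
from fractions import Fraction


def brute_partial_sum_entropy(x) -> float:
    """Entropy of the normalised partial sums, computed with exact
    rational partial sums before the final log step."""
    partial = []
    running = Fraction(0)
    for value in x:
        running += Fraction(value).limit_denominator(10**9) if not isinstance(
            value, (int, Fraction)
        ) else Fraction(value)
        partial.append(running)
    z = sum(partial)
    if z == 0:
        return 0.0
    h = 0.0
    for s in partial:
        p = s / z
        if p > 0:
            h -= float(p) * math.log2(float(p))
    return h


def brute_lf_sequence(indicator):
    """Local-frequency sequence of a 0/1 indicator row: reciprocal gaps
    placed at occurrence positions (P_0 = 0), zeros elsewhere."""
    out = [Fraction(0)] * len(indicator)
    previous = 0
    for index, bit in enumerate(indicator, start=1):
        if bit:
            out[index - 1] = Fraction(1, index - previous)
            previous = index
    return out


def brute_lf_entropy(indicator) -> float:
    """LF-based partial-sum entropy of a 0/1 indicator row."""
    return brute_partial_sum_entropy(brute_lf_sequence(indicator))
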