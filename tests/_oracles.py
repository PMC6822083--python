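"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: quartiles by
explicit sort-and-interpolate, the hypergeometric tail by exhaustive
subset enumeration, and BH by the literal step-up recursion.
"""

from __future__ import annotations

import math
from itertools import combinations


def interpolated_quantile(values, q: float) -> float:
    """Linear interpolation between order statistics (type 7)."""
    s = sorted(float(v) for v in values)
    if not s:
        raise ValueError("empty cohort")
    h = (len(s) - 1) * q
    lo = math.floor(h)
    frac = h - lo
    if frac == 0:
        return s[lo]
    return s[lo] + frac * (s[lo + 1] - s[lo])


def tukey_fence(values, multiplier: float = 1.5) -> tuple[float, float, float]:
    """(q1, q3, upper fence) by the sort-and-interpolate oracle."""
    q1 = interpolated_quantile(values, 0.25)
    q3 = interpolated_quantile(values, 0.75)
    return q1, q3, q3 + multiplier * (q3 - q1)


def hypergeom_tail_by_enumeration(overlap: int, list_size: int, set_size: int, universe_size: int) -> float:
    """P(X >= overlap) by enumerating every possible gene list.

    Feasible only for tiny universes; the point is full independence from
    any distribution function.
    """
    universe = range(universe_size)
    members = set(range(set_size))
    total = 0
    hits = 0
    for draw in combinations(universe, list_size):
        total += 1
        if len(members.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


def bh_step_up(p_values) -> list[float]:
    """Benjamini-Hochberg adjusted values by the literal step-up formula."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        value = min(1.0, p_values[idx] * m / rank)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted
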