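"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's code paths: point probabilities
come from the plain factorial formula over exact integers, tails from
explicit enumeration of all tables sharing the observed margins, and the
GO tail from enumeration over query draws.
"""

from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import factorial


@lru_cache(maxsize=None)
def _f(x: int) -> int:
    return factorial(x)


def point_prob(a: int, b: int, c: int, d: int) -> Fraction:
    n = a + b + c + d
    num = _f(a + b) * _f(c + d) * _f(a + c) * _f(b + d)
    den = _f(a) * _f(b) * _f(c) * _f(d) * _f(n)
    return Fraction(num, den)


def admissible_a(a: int, b: int, c: int, d: int) -> range:
    n = a + b + c + d
    r, k = a + b, a + c
    return range(max(0, r + k - n), min(r, k) + 1)


def fisher_right_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """Sum of point probabilities over every table with the same margins
    and first cell >= a."""
    r, k = a + b, a + c
    n = a + b + c + d
    total = Fraction(0)
    for a2 in admissible_a(a, b, c, d):
        if a2 >= a:
            total += point_prob(a2, r - a2, k - a2, n - r - k + a2)
    return total


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int,
                                  max_enumerate: int = 30) -> Fraction:
    """P(|query ∩ annotated| >= k) by enumerating every size-n query draw
    from an N-gene universe with K annotated genes. Exact and slow."""
    assert N <= max_enumerate
    universe = range(N)
    annotated = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def bh_step_up(pvals):
    """Direct Benjamini-Hochberg step-up evaluation."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(1.0, pvals[idx] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted
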