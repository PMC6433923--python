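"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries' test routines) they
check: the Fisher oracle enumerates every 2x2 table with the observed
margins using exact integer combinatorics.
"""

import math


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration with integer weights.

    Each table with the same margins has probability proportional to
    C(r1, k) * C(r2, c1 - k); comparisons between integer weights are exact,
    so tie handling is unambiguous.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    return sum(w for w in weights if w <= w_obs) / denom


def canonical_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Representative of the symmetry orbit (row/col swaps, transpose)."""
    variants = [
        (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
        (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
    ]
    return min(variants)
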