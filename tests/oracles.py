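"""Independent exact-arithmetic oracles used only by the test suite.

These deliberately avoid the package's log-space code paths: everything is
integer combinatorics (math.comb) and exact rationals, so they can serve
as ground truth for the floating-point implementations.
"""

from fractions import Fraction
from math import comb

# same relative tolerance the package applies to the two-sided "as or more
# extreme" comparison, expressed exactly in integer arithmetic
_TOL_NUM = 10**9 + 100  # num_j * 1e9 <= num_obs * (1e9 + 100)  <=>  <= (1 + 1e-7)
_TOL_DEN = 10**9


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration over tables with the observed
    margins, summing point probabilities <= the observed one (with the same
    1e-7 relative tolerance the implementation uses), as an exact rational."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, j) * comb(r2, c1 - j) for j in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(x for x in nums if x * _TOL_DEN <= obs * _TOL_NUM)
    return Fraction(total, comb(n, c1))


def hypergeom_pmf_exact(j: int, N: int, K: int, n: int) -> Fraction:
    return Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))


def hypergeom_upper_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by direct pmf summation in exact rational arithmetic."""
    hi = min(K, n)
    denom = comb(N, n)
    total = sum(comb(K, j) * comb(N - K, n - j) for j in range(max(k, 0), hi + 1))
    return Fraction(total, denom)


def bh_adjust_naive(p_values):
    """Direct O(m^2) Benjamini-Hochberg definition: q_i is the smallest
    m * p_j / rank(p_j) over all thresholds p_j >= p_i, capped at 1.
    None marks a missing (untested) entry."""
    tested = [p for p in p_values if p is not None]
    m = len(tested)
    out = []
    for p in p_values:
        if p is None:
            out.append(None)
            continue
        q = 1.0
        for t in tested:
            if t >= p:
                rank = sum(1 for x in tested if x <= t)
                q = min(q, t * m / rank)
        out.append(min(q, 1.0))
    return out
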