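"""Shared log-space combinatorics for the exact tests.

Everything is computed through lgamma so that population sizes in the
tens of thousands (and tail probabilities around 1e-35) neither overflow
nor underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def log_binom(n, k):
    """log C(n, k), vectorized; -inf outside 0 <= k <= n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k >= 0) & (k <= n), out, -np.inf)


def log_hypergeom_pmf(j, N, K, n):
    """log P(X = j) for X ~ Hypergeometric(N, K, n), vectorized over j."""
    return log_binom(K, j) + log_binom(N - K, n - j) - log_binom(N, n)


def hypergeom_support(N, K, n):
    """Inclusive support bounds (lo, hi) of Hypergeometric(N, K, n)."""
    return max(0, K + n - N), min(K, n)
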