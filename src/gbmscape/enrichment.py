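"""Annotation-overlap statistics and hypergeometric gene-set enrichment.

The enrichment statistic is the upper tail P(X >= k) of a hypergeometric
distribution: drawing a sample of n genes from a population of N that
contains K "success" genes, how surprising is observing k or more
successes in the sample.  Probabilities are computed in log space
(lgamma-based binomials) and the tail is accumulated from its smallest
terms, so populations of tens of thousands of genes and tails around
1e-35 are handled at full double precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from ._numeric import hypergeom_support, log_hypergeom_pmf
from .errors import ValidationError
from .io import GenomicInterval


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric test inputs and its upper-tail probability."""

    population_size: int   # N
    population_successes: int  # K
    sample_size: int       # n
    sample_successes: int  # k
    p_upper: float         # P(X >= k)

    def __post_init__(self):
        N, K, n, k = (self.population_size, self.population_successes,
                      self.sample_size, self.sample_successes)
        if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
            raise ValidationError(
                f"invalid hypergeometric inputs N={N}, K={K}, n={n}, k={k}"
            )
        if not (0 < self.p_upper <= 1):
            raise ValidationError(f"p_upper must be in (0, 1], got {self.p_upper}")


def hypergeom_upper_tail(N: int, K: int, n: int, k) -> float | np.ndarray:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` may be a scalar or an array of thresholds.  Values of k below the
    lower edge of the support give exactly 1.  Relative accuracy is well
    below 1e-6 across the support.
    """
    for name, v in (("N", N), ("K", K), ("n", n)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v}")
    N, K, n = int(N), int(K), int(n)
    if not (K <= N and n <= N):
        raise ValidationError(f"need K <= N and n <= N, got N={N}, K={K}, n={n}")
    karr = np.atleast_1d(np.asarray(k))
    if np.any(karr != np.floor(karr)):
        raise ValidationError("k must be integral")
    karr = karr.astype(np.int64)
    if (karr < 0).any() or (karr > min(K, n)).any():
        raise ValidationError(
            f"k must lie in [0, min(K, n)] = [0, {min(K, n)}], got {k}"
        )
    lo, hi = hypergeom_support(N, K, n)
    j = np.arange(lo, hi + 1)
    logp = log_hypergeom_pmf(j, N, K, n)
    # suffix log-sum accumulated from the top of the support: small tail
    # terms are added first, preserving relative accuracy
    suffix = np.logaddexp.accumulate(logp[::-1])[::-1]
    idx = np.clip(karr - lo, 0, hi - lo)
    out = np.where(karr <= lo, 0.0, suffix[idx])  # log(1) = 0 below support
    out = np.minimum(np.exp(out), 1.0)
    if np.isscalar(k) or np.asarray(k).ndim == 0:
        return float(out[0])
    return out


def _build_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_fraction(query: Sequence[GenomicInterval],
                     targets: Sequence[GenomicInterval],
                     by: str = "query") -> float:
    """Fraction of intervals having >= 1 bp overlap with the other set.

    ``by='query'`` (default): fraction of query intervals hit by any
    target.  ``by='target'``: fraction of target intervals hit by any
    query (the symmetric variant, e.g. "what fraction of TEs is overlapped
    by a DMR").  Intersection is half-open: touching intervals do not
    overlap.
    """
    if by not in ("query", "target"):
        raise ValidationError(f"by must be 'query' or 'target', got {by!r}")
    if by == "target":
        query, targets = targets, query
    if len(query) == 0:
        raise ValidationError("overlap fraction is undefined for an empty query set")
    trees = _build_tree(targets)
    hit = sum(
        1 for iv in query
        if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)
    )
    return hit / len(query)


def gene_set_enrichment(sample_ids: Iterable[str], success_ids: Iterable[str],
                        population_ids: Iterable[str],
                        strict: bool = True) -> EnrichmentResult:
    """Hypergeometric enrichment of a success set within a sampled gene set.

    In strict mode (default) any sample or success id outside the
    population raises, naming the offending ids; in lenient mode they are
    dropped with a warning.
    """
    population = set(population_ids)
    sample = set(sample_ids)
    success = set(success_ids)
    if not population:
        raise ValidationError("population is empty")
    stray_sample = sample - population
    stray_success = success - population
    if stray_sample or stray_success:
        msg = (
            f"ids outside the population: sample={sorted(stray_sample)[:10]}, "
            f"successes={sorted(stray_success)[:10]}"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg + " (dropped)")
        sample &= population
        success &= population
    N, K, n = len(population), len(success), len(sample)
    k = len(sample & success)
    p = hypergeom_upper_tail(N, K, n, k)
    return EnrichmentResult(population_size=N, population_successes=K,
                            sample_size=n, sample_successes=k, p_upper=float(p))
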