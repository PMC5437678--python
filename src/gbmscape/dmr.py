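"""Hypomethylated-region (hypo-DMR) calling.

The procedure: bin the genome into fixed tiles (default 100 bp), drop
tiles with fewer than 20 C+T calls in either sample of a comparison, test
each remaining tile with a two-sided Fisher's exact test on the pooled
(methylated, unmethylated) counts, Benjamini–Hochberg-adjust within each
replicate, keep tiles with q < 0.01 *and* an absolute methylation
reduction of at least 0.20 in *every* knockdown replicate, and finally
merge retained tiles lying within 200 bp of each other into regions.

Only hypomethylation (WT level minus knockdown level >= min_delta) is
selected; the Fisher p-value itself is direction-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._numeric import hypergeom_support, log_hypergeom_pmf
from .errors import ValidationError
from .io import GenomicInterval
from .methylation import TileCountSet, aggregate_to_tiles, methylation_level, tile_genome

logger = logging.getLogger(__name__)

#: relative tolerance of the "as or more extreme" comparison in the
#: two-sided Fisher test (guards float noise in tied point probabilities)
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class DmrParams:
    """Parameters of the hypo-DMR procedure (defaults are the study's)."""

    tile_size: int = 100
    min_calls: int = 20
    fdr: float = 0.01
    min_delta: float = 0.20
    merge_gap: int = 200
    n_required_reps: int = 2
    coverage_filter: str = "pair"  # or "all": >= min_calls in every sample

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValidationError(f"fdr must be in (0, 1), got {self.fdr}")
        if not 0 < self.min_delta <= 1:
            raise ValidationError(f"min_delta must be in (0, 1], got {self.min_delta}")
        if self.tile_size <= 0 or self.min_calls < 0 or self.merge_gap < 0:
            raise ValidationError("tile_size > 0, min_calls >= 0, merge_gap >= 0 required")
        if self.n_required_reps < 1:
            raise ValidationError("n_required_reps must be >= 1")
        if self.coverage_filter not in ("pair", "all"):
            raise ValidationError("coverage_filter must be 'pair' or 'all'")


@dataclass(frozen=True)
class DMR:
    """A merged hypomethylated region.

    ``delta`` is the WT-minus-kd weighted methylation difference pooled
    over the merged span (kd replicates summed); ``min_q`` the smallest
    BH-adjusted p among the constituent selected tiles across replicates.
    """

    interval: GenomicInterval
    context: str
    n_tiles: int
    delta: float
    min_q: float


@dataclass
class TileTestResult:
    """Per-tile Fisher test outcome for one WT-vs-kd replicate comparison."""

    tiles: list[GenomicInterval]
    context: str
    p: np.ndarray       # raw two-sided Fisher p; NaN where untested
    q: np.ndarray       # BH-adjusted over tested tiles; NaN where untested
    delta: np.ndarray   # WT level - kd level; NaN where either side uncovered
    tested: np.ndarray  # bool

    @property
    def n_tested(self) -> int:
        return int(self.tested.sum())


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table ((a, b), (c, d)).

    Rows are (n_meth, n_unmeth) for the two samples.  The p-value sums the
    probabilities of all tables with the observed margins whose point
    probability is <= that of the observed table (relative tolerance 1e-7
    on the comparison).  A degenerate table (any zero margin) has a single
    possible outcome and returns 1.0.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError(f"table entries must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    if N == 0:
        logger.debug("degenerate all-zero Fisher table; p = 1 by convention")
        return 1.0
    lo, hi = hypergeom_support(N, r1, c1)
    j = np.arange(lo, hi + 1)
    logp = log_hypergeom_pmf(j, N, r1, c1)
    log_obs = logp[a - lo]
    # compare in log space: log p_j <= log p_obs + log(1 + tol)
    keep = logp <= log_obs + np.log1p(_FISHER_REL_TOL)
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    ``p_values`` may contain NaN for untested entries; those propagate as
    NaN and do not count toward the number of tests m.  Output order
    matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def test_tiles(wt: TileCountSet, kd: TileCountSet, params: DmrParams = DmrParams(),
               wt_label: str | None = None, kd_label: str | None = None,
               extra_tested_mask: np.ndarray | None = None) -> TileTestResult:
    """Fisher-test every sufficiently covered tile of a WT-vs-kd pair.

    Tiles with fewer than ``params.min_calls`` C+T calls in either sample
    are untested (NaN p/q).  ``extra_tested_mask`` further restricts the
    tested set (used by the strict all-samples coverage mode).
    """
    if wt.context != kd.context:
        raise ValidationError(f"context mismatch: {wt.context} vs {kd.context}")
    if len(wt.tiles) != len(kd.tiles) or any(
        (x.chrom, x.start, x.end) != (y.chrom, y.start, y.end)
        for x, y in zip(wt.tiles, kd.tiles)
    ):
        raise ValidationError("WT and kd tile lists do not match")

    def _single(cs: TileCountSet, label):
        if label is None:
            if len(cs.samples) != 1:
                raise ValidationError("sample label required when a TileCountSet holds several samples")
            label = next(iter(cs.samples))
        return cs.samples[label]

    wt_m, wt_u = _single(wt, wt_label)
    kd_m, kd_u = _single(kd, kd_label)
    tested = ((wt_m + wt_u) >= params.min_calls) & ((kd_m + kd_u) >= params.min_calls)
    if extra_tested_mask is not None:
        tested = tested & np.asarray(extra_tested_mask, dtype=bool)
    delta = methylation_level(wt_m, wt_u) - methylation_level(kd_m, kd_u)
    p = np.full(len(wt.tiles), np.nan)
    idx = np.flatnonzero(tested)
    for i in idx:
        p[i] = fisher_exact_2x2(int(wt_m[i]), int(wt_u[i]), int(kd_m[i]), int(kd_u[i]))
    q = bh_adjust(p)
    return TileTestResult(tiles=wt.tiles, context=wt.context, p=p, q=q,
                          delta=delta, tested=tested)


def select_hypo_tiles(results: list[TileTestResult], params: DmrParams = DmrParams()) -> np.ndarray:
    """Indices of tiles meeting q < fdr and delta >= min_delta in *every*
    provided replicate comparison (hypomethylation only)."""
    if len(results) < params.n_required_reps:
        raise ValidationError(
            f"need at least {params.n_required_reps} replicate results, got {len(results)}"
        )
    n = len(results[0].tiles)
    if any(len(r.tiles) != n for r in results):
        raise ValidationError("replicate results cover different tile lists")
    selected = np.ones(n, dtype=bool)
    for r in results:
        with np.errstate(invalid="ignore"):
            ok = r.tested & (r.q < params.fdr) & (r.delta >= params.min_delta)
        ok &= ~np.isnan(r.q) & ~np.isnan(r.delta)
        selected &= ok
    return np.flatnonzero(selected)


def merge_selected_tiles(tiles: list[GenomicInterval], merge_gap: int = 200):
    """Transitively merge same-chromosome tiles whose edge-to-edge gap is
    <= merge_gap (adjacent or overlapping tiles always merge).

    Returns a list of (chrom, start, end, member_indices) in genomic order;
    resulting spans are pairwise separated by more than merge_gap.
    """
    order = sorted(range(len(tiles)), key=lambda i: (tiles[i].chrom, tiles[i].start, tiles[i].end))
    merged = []
    for i in order:
        t = tiles[i]
        if merged and merged[-1][0] == t.chrom and t.start - merged[-1][2] <= merge_gap:
            chrom, start, end, members = merged[-1]
            merged[-1] = (chrom, start, max(end, t.end), members + [i])
        else:
            merged.append((t.chrom, t.start, t.end, [i]))
    return merged


def call_dmrs(wt_records: pd.DataFrame, kd_replicates: list[pd.DataFrame],
              chrom_sizes: dict[str, int], context: str = "CG",
              params: DmrParams = DmrParams(),
              return_details: bool = False):
    """Run the full hypo-DMR procedure.

    ``wt_records`` is a single (pooled) WT cytosine table; ``kd_replicates``
    are >= params.n_required_reps independent knockdown replicate tables.
    Returns a list of :class:`DMR` in genomic order (and the per-replicate
    :class:`TileTestResult` list when ``return_details``).
    """
    if len(kd_replicates) < params.n_required_reps:
        raise ValidationError(
            f"need >= {params.n_required_reps} kd replicates, got {len(kd_replicates)}"
        )
    tiles = tile_genome(chrom_sizes, params.tile_size)
    wt_counts = aggregate_to_tiles(wt_records, tiles, context, "WT")
    kd_counts = [
        aggregate_to_tiles(rep, tiles, context, f"kd_rep{i + 1}")
        for i, rep in enumerate(kd_replicates)
    ]

    extra_mask = None
    if params.coverage_filter == "all":
        extra_mask = wt_counts.coverage("WT") >= params.min_calls
        for i, cs in enumerate(kd_counts):
            extra_mask &= cs.coverage(f"kd_rep{i + 1}") >= params.min_calls

    results = [
        test_tiles(wt_counts, cs, params, extra_tested_mask=extra_mask)
        for cs in kd_counts
    ]
    selected = select_hypo_tiles(results, params)
    sel_tiles = [tiles[i] for i in selected]
    merged = merge_selected_tiles(sel_tiles, params.merge_gap)

    # pooled counts over each merged span: WT vs replicate-summed kd
    wt_m, wt_u = wt_counts.samples["WT"]
    kd_m = sum(cs.samples[lbl][0] for cs in kd_counts for lbl in cs.samples)
    kd_u = sum(cs.samples[lbl][1] for cs in kd_counts for lbl in cs.samples)
    starts = {}
    for gi, t in enumerate(tiles):
        starts.setdefault(t.chrom, []).append((t.start, t.end, gi))
    dmrs = []
    for k, (chrom, start, end, members) in enumerate(merged):
        span_idx = [gi for (s, e, gi) in starts[chrom] if s < end and e > start]
        sm = int(wt_m[span_idx].sum())
        su = int(wt_u[span_idx].sum())
        km = int(kd_m[span_idx].sum())
        ku = int(kd_u[span_idx].sum())
        delta = methylation_level(sm, su) - methylation_level(km, ku)
        member_global = [int(selected[m]) for m in members]
        min_q = min(float(r.q[g]) for r in results for g in member_global)
        interval = GenomicInterval(chrom, start, end, ".", f"dmr_{k + 1:05d}", "dmr")
        dmrs.append(DMR(interval=interval, context=context, n_tiles=len(members),
                        delta=float(delta), min_q=min_q))
    if return_details:
        return dmrs, results
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Tabular view of a DMR list (one row per region)."""
    return pd.DataFrame(
        [
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "id": d.interval.id,
                "context": d.context,
                "n_tiles": d.n_tiles,
                "delta": d.delta,
                "min_q": d.min_q,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "id", "context", "n_tiles", "delta", "min_q"],
    )


def write_dmrs(dmrs: list[DMR], path) -> None:
    """Write DMRs as BED6 plus (context, n_tiles, delta, min_q) columns;
    the BED score column carries round(delta * 1000)."""
    with open(path, "w") as fh:
        for d in dmrs:
            iv = d.interval
            score = int(round(d.delta * 1000))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{score}\t{iv.strand}"
                f"\t{d.context}\t{d.n_tiles}\t{d.delta:.6g}\t{d.min_q:.6g}\n"
            )
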