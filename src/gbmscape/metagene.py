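"""Metagene (TSS-to-TES scaled) profiling of methylation and coverage signal.

Every gene is mapped onto a common axis: an upstream flank, the gene body,
and a downstream flank, where each flank is scaled to the same *genomic*
length as the gene body before binning, so a 2-kb gene contributes 2-kb
flanks and a 600-bp gene 600-bp flanks.  Minus-strand genes are reversed so
the axis always runs 5' -> 3'.  Genes are grouped (typically into
expression quintiles) and each group's profile is the unweighted mean over
its genes, bin by bin.

Bin values are computed with fractional base-to-bin overlap weights, which
makes profiles exactly symmetric under coordinate mirroring + strand flip.
Methylation bins pool counts (sum #C / sum (#C+#T)) before the across-gene
average; coverage bins take the mean per-base signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CONTEXTS, GenomicInterval, SignalTrack

QUINTILE_LABELS = ("Q1", "Q2", "Q3", "Q4", "Q5")

#: default expression threshold for calling a gene "expressed" (FPKM)
EXPRESSED_FPKM = 0.5


@dataclass
class MetageneProfile:
    """Binned mean signal over upstream/body/downstream, per gene group."""

    n_bins_body: int
    n_bins_flank: int
    groups: list[str]
    values: np.ndarray          # groups x (2*n_bins_flank + n_bins_body)
    n_genes: np.ndarray         # genes profiled per group
    skipped: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return 2 * self.n_bins_flank + self.n_bins_body

    @property
    def segments(self) -> np.ndarray:
        """Segment label ('up', 'body', 'down') per column."""
        return np.array(
            ["up"] * self.n_bins_flank + ["body"] * self.n_bins_body + ["down"] * self.n_bins_flank
        )

    def body(self, group: str) -> np.ndarray:
        i = self.groups.index(group)
        return self.values[i, self.n_bins_flank: self.n_bins_flank + self.n_bins_body]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        seg = self.segments
        for gi, g in enumerate(self.groups):
            for b in range(self.n_bins):
                rows.append((g, b, seg[b], self.values[gi, b], int(self.n_genes[gi])))
        return pd.DataFrame(rows, columns=["group", "bin", "segment", "mean", "n_genes"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def assign_quintiles(expr: Mapping[str, float], gene_ids: Sequence[str],
                     n_groups: int = 5) -> dict[str, str]:
    """Partition genes into expression quintiles Q1 (lowest) .. Q5 (highest).

    Genes are sorted ascending by FPKM with ties broken by lexicographic
    gene id, then cut into groups whose sizes differ by at most one; when
    sizes are unequal the extra genes go to the low quintiles, so for
    n < 5 groups fill from Q1 upward and high quintiles stay empty.
    """
    missing = [g for g in gene_ids if g not in expr]
    if missing:
        raise ValidationError(f"genes absent from expression table: {missing[:10]}")
    ordered = sorted(gene_ids, key=lambda g: (expr[g], g))
    n = len(ordered)
    base, rem = divmod(n, n_groups)
    out = {}
    start = 0
    for gi in range(n_groups):
        size = base + (1 if gi < rem else 0)
        for g in ordered[start:start + size]:
            out[g] = QUINTILE_LABELS[gi] if n_groups == 5 else f"Q{gi + 1}"
        start += size
    return out


def expression_quintile_grouping(expr: Mapping[str, float], genes: Sequence[GenomicInterval],
                                 min_fpkm: float | None = EXPRESSED_FPKM) -> dict[str, str]:
    """Quintile grouping restricted to expressed genes (FPKM > min_fpkm).

    Pass ``min_fpkm=None`` to include all genes.  Genes below the threshold
    are absent from the returned mapping (and thus not profiled).
    """
    ids = [g.id for g in genes]
    if min_fpkm is not None:
        missing = [g for g in ids if g not in expr]
        if missing:
            raise ValidationError(f"genes absent from expression table: {missing[:10]}")
        ids = [g for g in ids if expr[g] > min_fpkm]
    return assign_quintiles(expr, ids)


def _unit_overlap(offsets: np.ndarray, seg_len: int, n_bins: int):
    """Split unit intervals [o, o+1) over equal bins of [0, seg_len).

    Requires seg_len >= n_bins (bin width >= 1) so each unit interval
    touches at most two bins.  Returns (bin0, w0, bin1, w1) arrays where the
    second contribution has w1 = 0 when the interval lies inside one bin.
    """
    o = np.asarray(offsets, dtype=np.int64)
    bin0 = (o * n_bins) // seg_len
    boundary = (bin0 + 1) * seg_len / n_bins
    inside = (o + 1) * n_bins <= (bin0 + 1) * seg_len  # integer-exact comparison
    w0 = np.where(inside, 1.0, boundary - o)
    bin1 = np.minimum(bin0 + 1, n_bins - 1)
    w1 = np.where(inside, 0.0, (o + 1) - boundary)
    return bin0, w0, bin1, w1


class MethylationSource:
    """Cytosine-count signal source for one context.

    Bin value = pooled weighted methylation level of the cytosines in the
    bin; NaN where no calls fall.
    """

    def __init__(self, records: pd.DataFrame, context: str = "CG"):
        if context not in CONTEXTS:
            raise ValidationError(f"unknown context {context!r}")
        self.context = context
        sub = records[records["context"] == context]
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos0 = grp["pos"].to_numpy() - 1
            order = np.argsort(pos0, kind="stable")
            self._by_chrom[chrom] = (
                pos0[order],
                grp["n_meth"].to_numpy()[order].astype(float),
                (grp["n_meth"] + grp["n_unmeth"]).to_numpy()[order].astype(float),
            )

    def segment_bins(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        pos0, meth, total = self._by_chrom.get(chrom, (np.empty(0, dtype=np.int64),) * 3)
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        p, m, t = pos0[lo:hi], meth[lo:hi], total[lo:hi]
        msum = np.zeros(n_bins)
        tsum = np.zeros(n_bins)
        if p.size:
            b0, w0, b1, w1 = _unit_overlap(p - start, end - start, n_bins)
            np.add.at(msum, b0, w0 * m)
            np.add.at(tsum, b0, w0 * t)
            np.add.at(msum, b1, w1 * m)
            np.add.at(tsum, b1, w1 * t)
        with np.errstate(invalid="ignore"):
            return np.where(tsum > 0, msum / np.where(tsum > 0, tsum, 1), np.nan)


class TrackSource:
    """Per-base coverage signal source; bin value = mean per-base signal."""

    def __init__(self, track: SignalTrack):
        self.track = track

    def segment_bins(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        vec = self.track.data.get(chrom)
        if vec is None:
            return np.full(n_bins, np.nan)
        seg = np.zeros(end - start)
        s, e = max(start, 0), min(end, vec.size)
        if e > s:
            seg[s - start:e - start] = vec[s:e]
        vals = np.zeros(n_bins)
        wsum = np.zeros(n_bins)
        b0, w0, b1, w1 = _unit_overlap(np.arange(end - start), end - start, n_bins)
        np.add.at(vals, b0, w0 * seg)
        np.add.at(wsum, b0, w0)
        np.add.at(vals, b1, w1 * seg)
        np.add.at(wsum, b1, w1)
        return vals / wsum


def gene_profile(source, gene: GenomicInterval, n_bins_body: int = 40,
                 n_bins_flank: int = 20, chrom_size: int | None = None) -> np.ndarray:
    """Binned signal vector (upstream, body, downstream) for one gene.

    Flanks have the same genomic length L as the gene body.  Bins whose
    interval extends outside [0, chrom_size) are NaN.  Raises if the gene
    is shorter than the bin count of any segment (callers skip such genes).
    """
    L = gene.length
    if L < max(n_bins_body, n_bins_flank):
        raise ValidationError(
            f"gene {gene.id!r} of length {L} is shorter than the bin count"
        )
    segments = [
        (gene.start - L, gene.start, n_bins_flank),
        (gene.start, gene.end, n_bins_body),
        (gene.end, gene.end + L, n_bins_flank),
    ]
    parts = []
    for s, e, nb in segments:
        vals = source.segment_bins(gene.chrom, s, e, nb)
        if s < 0 or (chrom_size is not None and e > chrom_size):
            # mark bins not fully inside the chromosome as missing
            edges = s + (e - s) * np.arange(nb + 1) / nb
            bad = (edges[:-1] < 0)
            if chrom_size is not None:
                bad |= edges[1:] > chrom_size
            vals = np.where(bad, np.nan, vals)
        parts.append(vals)
    vec = np.concatenate(parts)
    if gene.strand == "-":
        vec = vec[::-1]
    return vec


def metagene(source, genes: Sequence[GenomicInterval], grouping: Mapping[str, str],
             n_bins_body: int = 40, n_bins_flank: int = 20,
             chrom_sizes: Mapping[str, int] | None = None,
             group_order: Sequence[str] | None = None) -> MetageneProfile:
    """Average per-gene profiles within groups.

    ``grouping`` maps gene id -> group label; genes absent from the mapping
    are not profiled.  Per group and bin the value is the unweighted mean
    over genes with a non-missing bin value.  Empty groups yield a NaN row
    with a warning.
    """
    if group_order is None:
        seen = sorted({g for g in grouping.values()})
        group_order = seen
    group_order = list(group_order)
    n_bins = 2 * n_bins_flank + n_bins_body
    sums = np.zeros((len(group_order), n_bins))
    counts = np.zeros((len(group_order), n_bins))
    n_genes = np.zeros(len(group_order), dtype=int)
    skipped: list[str] = []
    gidx = {g: i for i, g in enumerate(group_order)}
    for gene in genes:
        label = grouping.get(gene.id)
        if label is None:
            continue
        if label not in gidx:
            raise ValidationError(f"gene {gene.id!r} mapped to unknown group {label!r}")
        size = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        try:
            vec = gene_profile(source, gene, n_bins_body, n_bins_flank, size)
        except ValidationError:
            skipped.append(gene.id)
            continue
        i = gidx[label]
        ok = ~np.isnan(vec)
        sums[i, ok] += vec[ok]
        counts[i, ok] += 1
        n_genes[i] += 1
    if skipped:
        warnings.warn(f"skipped {len(skipped)} genes shorter than the bin count")
    for g, n in zip(group_order, n_genes):
        if n == 0:
            warnings.warn(f"group {g!r} contains no profiled genes; row is missing")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return MetageneProfile(n_bins_body=n_bins_body, n_bins_flank=n_bins_flank,
                           groups=group_order, values=values, n_genes=n_genes,
                           skipped=skipped)


def normalize_track(track: SignalTrack) -> SignalTrack:
    """Scale a raw count track to counts per million mapped reads."""
    if track.total_reads is None or track.total_reads <= 0:
        raise ValidationError("normalize_track requires total_reads > 0")
    factor = 1e6 / track.total_reads
    return SignalTrack(
        data={c: v * factor for c, v in track.data.items()},
        total_reads=track.total_reads,
    )


def differential_profile(kd: MetageneProfile, wt: MetageneProfile,
                         mode: str = "difference") -> MetageneProfile:
    """kd-versus-WT differential profile, element-wise.

    ``difference``: kd - wt.  ``log2_ratio``: log2((kd+eps)/(wt+eps)) with
    eps = 1% of the global mean signal (guards empty bins).  Missing values
    propagate.
    """
    if mode not in ("difference", "log2_ratio"):
        raise ValidationError(f"unknown mode {mode!r}")
    if (kd.n_bins_body, kd.n_bins_flank, kd.groups) != (wt.n_bins_body, wt.n_bins_flank, wt.groups):
        raise ValidationError("profiles have different bin/group structure")
    if mode == "difference":
        values = kd.values - wt.values
    else:
        eps = 0.01 * np.nanmean(np.concatenate([kd.values.ravel(), wt.values.ravel()]))
        if not np.isfinite(eps) or eps <= 0:
            eps = 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.log2((kd.values + eps) / (wt.values + eps))
    return MetageneProfile(n_bins_body=kd.n_bins_body, n_bins_flank=kd.n_bins_flank,
                           groups=list(kd.groups), values=values,
                           n_genes=kd.n_genes.copy())


def plot_profile(profile: MetageneProfile, path, title: str = "") -> None:
    """Convenience line plot of a profile (one line per group)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(profile.n_bins)
    for i, g in enumerate(profile.groups):
        ax.plot(x, profile.values[i], label=f"{g} (n={profile.n_genes[i]})")
    for edge in (profile.n_bins_flank, profile.n_bins_flank + profile.n_bins_body):
        ax.axvline(edge - 0.5, color="grey", lw=0.5, ls="--")
    ax.set_xticks([0, profile.n_bins_flank, profile.n_bins_flank + profile.n_bins_body,
                   profile.n_bins - 1])
    ax.set_xticklabels(["-1x", "TSS", "TES", "+1x"])
    ax.set_ylabel("mean signal")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
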