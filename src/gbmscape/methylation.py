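"""Weighted methylation levels and aggregation of cytosine calls into tiles.

The unit statistic everywhere is the *weighted* methylation level
``#C / (#C + #T)`` computed on pooled counts — never a mean of per-cytosine
ratios (that alternative is exposed as an option on
:func:`region_methylation`).  Plus- and minus-strand cytosines are pooled;
no CG-dyad pairing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CONTEXTS, GenomicInterval


@dataclass
class TileCountSet:
    """Per-tile methylation call sums for one context across samples.

    ``samples`` maps a sample label to a pair of int arrays
    (n_meth_sum, n_unmeth_sum), each aligned to ``tiles``.
    """

    tiles: list[GenomicInterval]
    context: str
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        n = len(self.tiles)
        for label, (m, u) in self.samples.items():
            if len(m) != n or len(u) != n:
                raise ValidationError(
                    f"sample {label!r}: count vectors must match the {n} tiles"
                )
            if (np.asarray(m) < 0).any() or (np.asarray(u) < 0).any():
                raise ValidationError(f"sample {label!r}: negative counts")

    def add_sample(self, label: str, n_meth: np.ndarray, n_unmeth: np.ndarray):
        if len(n_meth) != len(self.tiles) or len(n_unmeth) != len(self.tiles):
            raise ValidationError("count vectors must match the tile list length")
        self.samples[label] = (np.asarray(n_meth), np.asarray(n_unmeth))

    def coverage(self, label: str) -> np.ndarray:
        """Total C+T calls per tile for one sample."""
        m, u = self.samples[label]
        return m + u

    def levels(self, label: str) -> np.ndarray:
        m, u = self.samples[label]
        return methylation_level(m, u)


def methylation_level(n_meth, n_unmeth):
    """Methylation level #C/(#C+#T); NaN where there are no calls.

    Accepts scalars or arrays; negative counts raise.
    """
    m = np.asarray(n_meth, dtype=float)
    u = np.asarray(n_unmeth, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValidationError("call counts must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, m / np.where(total > 0, total, 1), np.nan)
    if np.isscalar(n_meth) and np.isscalar(n_unmeth):
        return float(level)
    return level


def tile_genome(chrom_sizes: dict[str, int], tile_size: int = 100) -> list[GenomicInterval]:
    """Bin the genome into fixed-size tiles, last tile truncated to the
    chromosome end.  Tiles are ordered by chromosome (input order) then
    position; ids are ``{chrom}:{start}-{end}``."""
    if tile_size <= 0:
        raise ValidationError(f"tile_size must be > 0, got {tile_size}")
    tiles = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValidationError(f"chromosome {chrom!r} has non-positive length {size}")
        for start in range(0, size, tile_size):
            end = min(start + tile_size, size)
            tiles.append(GenomicInterval(chrom, start, end, ".", f"{chrom}:{start}-{end}", "tile"))
    return tiles


def _tile_index(tiles: list[GenomicInterval]):
    """Per-chromosome sorted (starts, ends, global index) arrays."""
    by_chrom: dict[str, list[int]] = {}
    for i, t in enumerate(tiles):
        by_chrom.setdefault(t.chrom, []).append(i)
    index = {}
    for chrom, idxs in by_chrom.items():
        starts = np.array([tiles[i].start for i in idxs])
        ends = np.array([tiles[i].end for i in idxs])
        order = np.argsort(starts, kind="stable")
        index[chrom] = (starts[order], ends[order], np.asarray(idxs)[order])
    return index


def aggregate_to_tiles(records: pd.DataFrame, tiles: list[GenomicInterval],
                       context: str, label: str = "sample") -> TileCountSet:
    """Sum cytosine call counts of one context into tiles (one sample).

    A cytosine at 1-based position ``pos`` falls in the tile containing the
    0-based coordinate ``pos - 1`` (the single conversion point of the
    package).  Strands are pooled.  Records on chromosomes absent from the
    tile list raise.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    out = TileCountSet(tiles=tiles, context=context)
    n_meth = np.zeros(len(tiles), dtype=np.int64)
    n_unmeth = np.zeros(len(tiles), dtype=np.int64)
    sub = records[records["context"] == context]
    index = _tile_index(tiles)
    unknown = set(sub["chrom"].unique()) - set(index)
    if unknown:
        raise ValidationError(
            f"records on chromosomes absent from the tile list: {sorted(unknown)}"
        )
    for chrom, grp in sub.groupby("chrom", sort=False):
        starts, ends, idxs = index[chrom]
        pos0 = grp["pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        inside = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        tgt = idxs[j[inside]]
        np.add.at(n_meth, tgt, grp["n_meth"].to_numpy()[inside])
        np.add.at(n_unmeth, tgt, grp["n_unmeth"].to_numpy()[inside])
    out.add_sample(label, n_meth, n_unmeth)
    return out


def region_methylation(records: pd.DataFrame, interval: GenomicInterval,
                       context: str, method: str = "pooled") -> float:
    """Weighted methylation level of one context over one region.

    ``pooled`` (default) divides summed #C by summed #C+#T over the
    contained cytosines; ``mean_of_ratios`` averages per-cytosine levels of
    covered cytosines instead.  NaN when the region contains no calls.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    if method not in ("pooled", "mean_of_ratios"):
        raise ValidationError(f"unknown method {method!r}")
    pos0 = records["pos"].to_numpy() - 1
    mask = (
        (records["context"] == context).to_numpy()
        & (records["chrom"] == interval.chrom).to_numpy()
        & (pos0 >= interval.start)
        & (pos0 < interval.end)
    )
    m = records["n_meth"].to_numpy()[mask]
    u = records["n_unmeth"].to_numpy()[mask]
    if method == "pooled":
        total = int(m.sum() + u.sum())
        return float(m.sum() / total) if total > 0 else float("nan")
    covered = (m + u) > 0
    if not covered.any():
        return float("nan")
    return float(np.mean(m[covered] / (m[covered] + u[covered])))
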