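"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate conventions are fixed here and never renegotiated downstream:

* intervals (BED, bedGraph) are 0-based half-open;
* cytosine positions are 1-based, as in per-cytosine bisulfite reports.

The single 1-based -> 0-based conversion happens inside the aggregation
operations in :mod:`gbmscape.methylation`.  All readers validate and reject
malformed rows with the offending line number rather than coercing silently.
Chromosome names are taken verbatim; there is no "Chr1"/"1" aliasing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ChromosomeMismatchError, FormatError, ValidationError

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")
INTERVAL_KINDS = ("gene", "TE", "h33_region", "tile", "dmr", "other")

#: column order of the cytosine report dialect
CYTOSINE_COLUMNS = ("chrom", "pos", "strand", "n_meth", "n_unmeth", "context")


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's identity and methylated/unmethylated call counts.

    ``n_meth`` is the number of reads calling C (methylated), ``n_unmeth``
    the number calling T (converted, unmethylated); the methylation level of
    the position is ``n_meth / (n_meth + n_unmeth)``.
    """

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"cytosine position must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"context must be one of {CONTEXTS}, got {self.context!r}"
            )
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError(
                f"call counts must be non-negative, got ({self.n_meth}, {self.n_unmeth})"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open annotated region; ``length = end - start``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    kind: str = "other"

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be +, - or ., got {self.strand!r}")
        if self.kind not in INTERVAL_KINDS:
            raise ValidationError(f"unknown interval kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Per-base non-negative signal per chromosome, plus the read total used
    for counts-per-million normalization."""

    data: dict[str, np.ndarray]
    total_reads: int | None = None

    def __post_init__(self):
        for chrom, vec in self.data.items():
            vec = np.asarray(vec, dtype=float)
            if (vec < 0).any():
                raise ValidationError(f"negative signal values on {chrom}")
            self.data[chrom] = vec
        if self.total_reads is not None and self.total_reads <= 0:
            raise ValidationError(
                f"total_reads must be a positive integer, got {self.total_reads}"
            )

    @property
    def chroms(self) -> list[str]:
        return list(self.data)


def _open_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a per-cytosine call table into a DataFrame.

    The dialect is TSV with columns (chrom, pos, strand, n_meth, n_unmeth,
    context).  An optional header row is detected by a non-numeric second
    field.  Rows are returned in file order with dtypes
    (object, int64, object, int64, int64, object).
    """
    chroms, poss, strands, meths, unmeths, contexts = [], [], [], [], [], []
    first = True
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(
                f"{path}: line {lineno}: expected 6 tab-separated columns "
                f"(chrom, pos, strand, n_meth, n_unmeth, context), got {len(fields)}"
            )
        if first:
            first = False
            try:
                int(fields[1])
            except ValueError:
                continue  # header row
        try:
            pos, n_meth, n_unmeth = int(fields[1]), int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer field: {exc}") from exc
        if pos < 1:
            raise ValidationError(f"{path}: line {lineno}: position must be >= 1, got {pos}")
        if n_meth < 0 or n_unmeth < 0:
            raise ValidationError(
                f"{path}: line {lineno}: negative call count ({n_meth}, {n_unmeth})"
            )
        if fields[2] not in STRANDS:
            raise ValidationError(f"{path}: line {lineno}: bad strand {fields[2]!r}")
        if fields[5] not in CONTEXTS:
            raise ValidationError(
                f"{path}: line {lineno}: bad context {fields[5]!r}, expected CG/CHG/CHH"
            )
        chroms.append(fields[0])
        poss.append(pos)
        strands.append(fields[2])
        meths.append(n_meth)
        unmeths.append(n_unmeth)
        contexts.append(fields[5])
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "pos": pd.Series(poss, dtype=np.int64),
            "strand": pd.Series(strands, dtype=object),
            "n_meth": pd.Series(meths, dtype=np.int64),
            "n_unmeth": pd.Series(unmeths, dtype=np.int64),
            "context": pd.Series(contexts, dtype=object),
        }
    )


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    """Write a cytosine call table in the dialect read_cytosine_report reads."""
    records.to_csv(path, sep="\t", header=False, index=False,
                   columns=list(CYTOSINE_COLUMNS))


def records_from_frame(frame: pd.DataFrame) -> list[CytosineRecord]:
    """Materialize DataFrame rows as validated CytosineRecord objects."""
    return [
        CytosineRecord(r.chrom, int(r.pos), r.strand, r.context,
                       int(r.n_meth), int(r.n_unmeth))
        for r in frame.itertuples(index=False)
    ]


def frame_from_records(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context)
            for r in records]
    return pd.DataFrame(rows, columns=list(CYTOSINE_COLUMNS)) if rows else pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in zip(
            CYTOSINE_COLUMNS, (object, np.int64, object, np.int64, np.int64, object))}
    )


def read_bed(path, kind: str = "other") -> list[GenomicInterval]:
    """Read BED3 or BED6 intervals (0-based half-open); strand '.' if absent."""
    if kind not in INTERVAL_KINDS:
        raise ValidationError(f"unknown interval kind {kind!r}")
    out = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: BED needs at least 3 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) > 3 else ""
        strand = fields[5] if len(fields) > 5 else "."
        try:
            out.append(GenomicInterval(fields[0], start, end, strand, name, kind))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path,
              scores: Mapping[int, float] | None = None) -> None:
    """Write intervals as BED6 (newline-terminated).

    ``scores`` maps interval index -> score.  DMR callers pass the
    methylation difference; it is encoded in the BED score column as
    ``round(delta * 1000)``, the documented convention for this package.
    """
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0
            if scores is not None and i in scores:
                score = int(round(scores[i] * 1000))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{score}\t{iv.strand}\n")


def read_expression_table(path) -> dict[str, float]:
    """Read a 2-column TSV of gene id -> FPKM into a dict (insertion order)."""
    table: dict[str, float] = {}
    first = True
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(
                f"{path}: line {lineno}: expected 2 columns (gene_id, fpkm)"
            )
        gene, raw = fields[0], fields[1]
        if first:
            first = False
            try:
                float(raw)
            except ValueError:
                continue  # header
        try:
            value = float(raw)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric FPKM {raw!r}") from exc
        if not np.isfinite(value) or value < 0:
            raise ValidationError(
                f"{path}: line {lineno}: FPKM must be finite and >= 0, got {raw}"
            )
        if gene in table:
            raise ValidationError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
        table[gene] = value
    return table


def write_expression_table(table: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        for gene, value in table.items():
            fh.write(f"{gene}\t{value:g}\n")


def read_bedgraph(path, total_reads: int | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into per-base vectors.

    Input intervals must not overlap (each base covered at most once);
    uncovered bases are 0.  Vector length per chromosome is the largest end
    coordinate seen.
    """
    spans: dict[str, list[tuple[int, int, float, int]]] = {}
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(
                f"{path}: line {lineno}: bedGraph needs 4 columns, got {len(fields)}"
            )
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad numeric field") from exc
        if start < 0 or start >= end:
            raise ValidationError(
                f"{path}: line {lineno}: invalid interval [{start}, {end})"
            )
        if value < 0:
            raise ValidationError(f"{path}: line {lineno}: negative signal {value}")
        spans.setdefault(fields[0], []).append((start, end, value, lineno))
    data: dict[str, np.ndarray] = {}
    for chrom, rows in spans.items():
        rows.sort(key=lambda r: (r[0], r[1]))
        prev_end, prev_line = -1, -1
        for start, end, _, lineno in rows:
            if start < prev_end:
                raise ValidationError(
                    f"{path}: line {lineno}: interval [{start}, {end}) on {chrom} "
                    f"overlaps the interval ending at {prev_end} (line {prev_line})"
                )
            prev_end, prev_line = end, lineno
        vec = np.zeros(rows[-1][1], dtype=float)
        for start, end, value, _ in rows:
            vec[start:end] = value
        data[chrom] = vec
    return SignalTrack(data=data, total_reads=total_reads)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a SignalTrack as bedGraph, merging equal-valued adjacent runs
    and omitting zero runs (value-level round trip with read_bedgraph)."""
    with open(path, "w") as fh:
        for chrom in track.data:
            vec = track.data[chrom]
            if vec.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column TSV of chromosome name -> length."""
    sizes: dict[str, int] = {}
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns (chrom, size)")
        try:
            size = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer size") from exc
        if size <= 0:
            raise ValidationError(f"{path}: line {lineno}: size must be > 0, got {size}")
        if fields[0] in sizes:
            raise ValidationError(f"{path}: line {lineno}: duplicate chromosome {fields[0]!r}")
        sizes[fields[0]] = size
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def check_same_chroms(names_a, names_b, label_a="first input", label_b="second input"):
    """Hard error if the two chromosome name sets are disjoint-in-part.

    Names must be identical as sets; the error lists the names unique to
    each side so the user can see the naming scheme mismatch.
    """
    set_a, set_b = set(names_a), set(names_b)
    if set_a != set_b:
        raise ChromosomeMismatchError(set_a - set_b, set_b - set_a, label_a, label_b)
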