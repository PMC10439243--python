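"""Ingest per-amplicon / per-interval read counts and aggregate onto the grid."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import IntervalGrid


class CountsError(ValueError):
    """Malformed counts input."""


@dataclass
class SampleCounts:
    """Raw per-record read counts for one sample (amplicon or interval resolution)."""

    sample_id: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    count: np.ndarray

    def __post_init__(self):
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.count) == n):
            raise CountsError("column length mismatch")
        if np.any(self.count < 0):
            bad = int(np.flatnonzero(self.count < 0)[0])
            raise CountsError(f"negative count at record {bad}")

    @property
    def n_records(self) -> int:
        return len(self.count)

    @property
    def total(self) -> int:
        return int(self.count.sum())


def read_counts_table(path, sample_id: str | None = None) -> SampleCounts:
    """Read a BED4-like counts table: chrom, start, end, count.

    A header line is detected by non-numeric second column; gzip input is
    handled transparently by pandas.  Records with identical coordinates are
    summed with a warning.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "count"],
            dtype={"chrom": str},
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise CountsError(f"cannot parse counts table {path}: {exc}") from exc
    # tolerate a header row
    if len(df) and not str(df.iloc[0]["start"]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    for col in ("start", "end", "count"):
        try:
            df[col] = pd.to_numeric(df[col], downcast=None).astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(bad[0]) + 1 if len(bad) else "?"
            raise CountsError(f"{path}: non-integer {col!r} at data line {line}") from exc
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise CountsError(f"{path}: negative count at data line {int(neg[0]) + 1}")
    dup = df.duplicated(subset=["chrom", "start", "end"], keep=False)
    if dup.any():
        warnings.warn(f"{path}: {int(dup.sum())} duplicate-coordinate rows summed", stacklevel=2)
        df = df.groupby(["chrom", "start", "end"], as_index=False, sort=False)["count"].sum()
    if sample_id is None:
        sample_id = _stem(path)
    return SampleCounts(
        sample_id=sample_id,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
        end=df["end"].to_numpy(),
        count=df["count"].to_numpy(),
    )


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    for suffix in (".gz", ".tsv", ".bed", ".txt"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base or "sample"


@dataclass
class IntervalVector:
    """Per-grid-interval counts for one sample."""

    sample_id: str
    grid: IntervalGrid
    counts: np.ndarray  # int64, length == grid.n_intervals
    dropped: int = 0  # reads whose midpoint fell outside every grid interval
    total_autosomal_coverage: int = field(init=False)

    def __post_init__(self):
        if len(self.counts) != self.grid.n_intervals:
            raise CountsError(
                f"vector length {len(self.counts)} != grid size {self.grid.n_intervals}"
            )
        self.total_autosomal_coverage = total_autosomal_coverage(self)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["count"] = self.counts
        return df


def bin_counts(sc: SampleCounts, grid: IntervalGrid) -> IntervalVector:
    """Assign each record's count to the grid interval containing its midpoint.

    Midpoint assignment gives every record exactly one bin, so counts are
    conserved: sum(vector) + dropped == sum(records).
    """
    counts = np.zeros(grid.n_intervals, dtype=np.int64)
    dropped = 0
    mid = (sc.start + sc.end) // 2
    # per-chromosome vectorized binning
    for chrom in np.unique(sc.chrom.astype(str)):
        rec_sel = np.flatnonzero(sc.chrom == chrom)
        grid_sel = np.flatnonzero(grid.chrom == chrom)
        if len(grid_sel) == 0:
            dropped += int(sc.count[rec_sel].sum())
            continue
        width = grid.width
        idx_on_chrom = mid[rec_sel] // width
        # grid bins on a chromosome are contiguous from 0, so position maps directly
        n_bins = len(grid_sel)
        in_range = idx_on_chrom < n_bins
        dropped += int(sc.count[rec_sel[~in_range]].sum())
        keep = rec_sel[in_range]
        np.add.at(counts, grid_sel[0] + idx_on_chrom[in_range].astype(np.int64), sc.count[keep])
    return IntervalVector(sample_id=sc.sample_id, grid=grid, counts=counts, dropped=dropped)


def total_autosomal_coverage(v: IntervalVector) -> int:
    """Total read count over scored autosomal intervals (the Coverage statistic)."""
    return int(v.counts[v.grid.scored].sum())
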