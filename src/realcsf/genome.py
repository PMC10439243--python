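"""Genome layout, chromosome-arm definitions, interval grid and focal gene windows.

All coordinates are 0-based, half-open internally (BED convention on disk).
Only autosomes participate in scoring; acrocentric p arms (which carry no
mappable amplicons) are excluded from the scored arm set, leaving 39 scored
arms for the standard 22-autosome human layout with 5 acrocentric
chromosomes (13, 14, 15, 21, 22).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_INTERVAL_WIDTH = 500_000
DEFAULT_FOCAL_FLANK = 1_000_000


class LayoutError(ValueError):
    """Raised when a genome layout file is malformed or inconsistent."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_start: int
    centromere_end: int
    acrocentric_p_arm: bool

    def __post_init__(self):
        if self.length <= 0:
            raise LayoutError(f"{self.name}: length must be > 0, got {self.length}")
        if not (0 <= self.centromere_start < self.centromere_end <= self.length):
            raise LayoutError(
                f"{self.name}: centromere [{self.centromere_start}, "
                f"{self.centromere_end}) must lie inside [0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered collection of autosomes with centromere annotations."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LayoutError(f"duplicate chromosome names: {dupes}")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self):
        return len(self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in layout")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm: p = [0, centromere_start), q = [centromere_end, length)."""

    chrom: str
    arm_label: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm_label}"


REQUIRED_LAYOUT_COLUMNS = ("name", "length", "centromere_start", "centromere_end", "acrocentric")


def load_genome_layout(path, one_based: bool = False) -> GenomeLayout:
    """Read a tab-separated layout file.

    Columns: name, length, centromere_start, centromere_end, acrocentric
    (0/1 flag for an acrocentric p arm).  Coordinates are 0-based half-open
    unless ``one_based`` is set, in which case start coordinates are shifted
    down by one on input.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    missing = [c for c in REQUIRED_LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"layout file {path} missing columns: {missing}")
    chroms = []
    for row in df.itertuples(index=False):
        cen_start = int(row.centromere_start) - (1 if one_based else 0)
        chroms.append(
            Chromosome(
                name=str(row.name),
                length=int(row.length),
                centromere_start=cen_start,
                centromere_end=int(row.centromere_end),
                acrocentric_p_arm=bool(int(row.acrocentric)),
            )
        )
    return GenomeLayout(chromosomes=tuple(chroms))


def load_default_layout() -> GenomeLayout:
    """Bundled hg19 autosome layout (UCSC centromere gap coordinates)."""
    ref = importlib.resources.files("realcsf.data") / "hg19_autosomes.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_genome_layout(p)


def enumerate_scored_arms(layout: GenomeLayout) -> list[ArmDefinition]:
    """All non-acrocentric autosomal arms in deterministic order.

    Order is layout chromosome order, p before q.  For the bundled hg19
    layout this yields exactly 39 arms.
    """
    arms: list[ArmDefinition] = []
    for c in layout:
        if not c.acrocentric_p_arm:
            arms.append(ArmDefinition(c.name, "p", 0, c.centromere_start))
        arms.append(ArmDefinition(c.name, "q", c.centromere_end, c.length))
    return arms


@dataclass(frozen=True)
class IntervalGrid:
    """Fixed-width tiling of the autosomes.

    Every full-width bin is kept; trailing partial bins are dropped.  Bins
    overlapping the centromere gap get ``arm_label`` "cen" and are never
    assigned to an arm.  ``scored`` marks bins belonging to one of the
    scored (non-acrocentric) arms; only those enter normalization and
    arm statistics.
    """

    layout: GenomeLayout
    width: int
    chrom: np.ndarray  # object array of chromosome names
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    arm_label: np.ndarray  # object: "p", "q" or "cen"
    scored: np.ndarray  # bool
    arm_names: tuple[str, ...] = field(default=())  # scored arm names, in order

    @property
    def n_intervals(self) -> int:
        return len(self.start)

    @property
    def arm_name_per_interval(self) -> np.ndarray:
        out = np.array([f"{c}{a}" for c, a in zip(self.chrom, self.arm_label)], dtype=object)
        out[~self.scored & (self.arm_label == "cen")] = "cen"
        return out

    def arm_interval_indices(self, arm_name: str) -> np.ndarray:
        """Indices (into the grid) of scored intervals on one arm."""
        full = self.arm_name_per_interval
        return np.flatnonzero(self.scored & (full == arm_name))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "arm": self.arm_name_per_interval,
                "scored": self.scored,
            }
        )


def build_interval_grid(layout: GenomeLayout, width: int = DEFAULT_INTERVAL_WIDTH) -> IntervalGrid:
    """Tile each autosome from position 0 in half-open ``width``-sized bins."""
    if width <= 0:
        raise ValueError(f"interval width must be > 0, got {width}")
    scored_arm_names = {a.name for a in enumerate_scored_arms(layout)}
    chroms, starts, ends, labels, scored = [], [], [], [], []
    for c in layout:
        n_bins = c.length // width
        for i in range(n_bins):
            s, e = i * width, (i + 1) * width
            if e <= c.centromere_start:
                lab = "p"
            elif s >= c.centromere_end:
                lab = "q"
            else:
                lab = "cen"  # overlaps the centromere gap
            chroms.append(c.name)
            starts.append(s)
            ends.append(e)
            labels.append(lab)
            scored.append(lab != "cen" and f"{c.name}{lab}" in scored_arm_names)
    ordered_arms = tuple(a.name for a in enumerate_scored_arms(layout))
    return IntervalGrid(
        layout=layout,
        width=width,
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        arm_label=np.array(labels, dtype=object),
        scored=np.array(scored, dtype=bool),
        arm_names=ordered_arms,
    )


@dataclass(frozen=True)
class FocalWindow:
    """Genomic window around an oncogene, with the grid intervals it overlaps."""

    gene_name: str
    chrom: str
    start: int
    end: int
    member_intervals: tuple[int, ...]

    @property
    def span(self) -> int:
        return self.end - self.start


def make_focal_window(
    gene_name: str,
    chrom: str,
    gene_start: int,
    gene_end: int,
    grid: IntervalGrid,
    flank: int = DEFAULT_FOCAL_FLANK,
) -> FocalWindow:
    """Window = gene body plus ``flank`` bp on either side, clipped to the chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if gene_end <= gene_start:
        raise ValueError("gene_end must be > gene_start")
    c = grid.layout.chromosome(chrom)  # KeyError if absent
    w_start = max(0, gene_start - flank)
    w_end = min(c.length, gene_end + flank)
    on_chrom = grid.chrom == chrom
    overlap = on_chrom & (grid.start < w_end) & (grid.end > w_start)
    return FocalWindow(
        gene_name=gene_name,
        chrom=chrom,
        start=w_start,
        end=w_end,
        member_intervals=tuple(int(i) for i in np.flatnonzero(overlap)),
    )


def load_focal_windows_bed(path, grid: IntervalGrid) -> list[FocalWindow]:
    """Read a BED4 file of pre-defined windows (chrom, start, end, gene)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"], comment="#")
    windows = []
    for row in df.itertuples(index=False):
        # window coordinates are taken verbatim (flank = 0 around the window)
        windows.append(
            make_focal_window(str(row.gene), str(row.chrom), int(row.start), int(row.end), grid, flank=0)
        )
    return windows


# The shipped four-gene focal panel uses fixed hg19 windows (gene body plus
# roughly 1 Mb flanks, rounded to 100-kb boundaries).  ERBB2 is also known
# as HER2; both names resolve to the same window.
def load_default_focal_windows(grid: IntervalGrid) -> list[FocalWindow]:
    ref = importlib.resources.files("realcsf.data") / "focal_windows.bed"
    with importlib.resources.as_file(ref) as p:
        return load_focal_windows_bed(p, grid)


FOCAL_GENE_SYNONYMS = {"HER2": "ERBB2"}
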