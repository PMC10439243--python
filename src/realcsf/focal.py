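"""Poisson Z scoring of focal oncogene amplification windows.

Observed read counts over a gene window are compared with the panel
expectation λ_gene = μ_gene × Coverage under a Poisson model:

    Z_gene = (Observed_gene − λ_gene) / sqrt(λ_gene)

Calling is one-sided: only amplifications (Z at or above the positivity
threshold) gate a positive call; focal losses are reported as negative Z
values but never drive positivity in the four-gene panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .counts import IntervalVector, SampleCounts
from .genome import FocalWindow
from .panel import PanelError, ReferencePanel, expected_gene_depth

DEFAULT_FOCAL_THRESHOLD = 7.5


@dataclass
class FocalScore:
    gene_name: str
    observed: int
    lam: float
    z: float | None
    positive: bool
    scorable: bool


def observed_gene_depth(sample, window: FocalWindow) -> int:
    """Summed read count over the window.

    Interval-resolution input (IntervalVector) sums the window's member grid
    intervals; amplicon-resolution input (SampleCounts) sums records whose
    midpoint lies inside the window.
    """
    if isinstance(sample, IntervalVector):
        idx = np.asarray(window.member_intervals, dtype=int)
        return int(sample.counts[idx].sum()) if len(idx) else 0
    if isinstance(sample, SampleCounts):
        mid = (sample.start + sample.end) // 2
        sel = (sample.chrom == window.chrom) & (mid >= window.start) & (mid < window.end)
        return int(sample.count[sel].sum())
    raise TypeError(f"unsupported sample type {type(sample).__name__}")


def focal_z(observed: int, lam: float) -> float:
    """Z_gene = (observed − λ) / sqrt(λ); requires λ > 0."""
    if lam <= 0:
        raise ValueError("lambda must be > 0 for a Poisson Z; gene is not scorable")
    return (observed - lam) / math.sqrt(lam)


def call_focal(z: float, threshold: float = DEFAULT_FOCAL_THRESHOLD) -> bool:
    """One-sided amplification call: positive iff z >= threshold."""
    return z >= threshold


def score_focal_windows(
    sample,
    panel: ReferencePanel,
    windows: list[FocalWindow],
    coverage: int,
    threshold: float = DEFAULT_FOCAL_THRESHOLD,
) -> list[FocalScore]:
    """Score every window of the focal panel for one sample."""
    out = []
    for w in windows:
        observed = observed_gene_depth(sample, w)
        try:
            lam = expected_gene_depth(panel, w, coverage)
        except PanelError:
            out.append(FocalScore(w.gene_name, observed, 0.0, None, False, False))
            continue
        if lam <= 0:
            out.append(FocalScore(w.gene_name, observed, lam, None, False, False))
            continue
        z = focal_z(observed, lam)
        out.append(FocalScore(w.gene_name, observed, lam, z, call_focal(z, threshold), True))
    return out
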