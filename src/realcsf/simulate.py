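"""Synthetic amplicon-count profiles with known copy-number truth.

The simulator emulates the data model of a repetitive-element amplicon
assay: a fixed per-interval amplification propensity (heterogeneous
amplicon efficiency, log-normal across intervals and shared by all samples
of a simulated "assay"), total-depth variation, and copy-number events
diluted by tumor fraction.  The expected read weight of interval i is

    w_i ∝ propensity_i × (1 + tf × (cn_i − 2) / 2)

— diploid-background mixing: a cell fraction ``tf`` carries ``cn_i`` copies
while the rest is diploid.  Counts are drawn per interval as Poisson (or
negative binomial when overdispersion > 0).

Propensities are non-zero only on scored intervals: centromeric gaps and
acrocentric p arms carry no mappable amplicons in the real assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import IntervalVector, SampleCounts, bin_counts
from .genome import FocalWindow, IntervalGrid

DEFAULT_DEPTH = 1_000_000
DEFAULT_EFFICIENCY_SD = 0.5


@dataclass
class ArmEvent:
    arm: str  # e.g. "chr7p"
    copy_number: int  # 0, 1, 3, 4 ...


@dataclass
class FocalEvent:
    window: FocalWindow
    copy_number: int  # up to ~50 for high-level amplifications


@dataclass
class SimulationConfig:
    seed: int = 0
    depth: int = DEFAULT_DEPTH
    efficiency_sd: float = DEFAULT_EFFICIENCY_SD
    overdispersion: float = 0.0
    tumor_fraction: float = 0.0
    arm_events: list[ArmEvent] = field(default_factory=list)
    focal_events: list[FocalEvent] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError(f"tumor_fraction must be in [0, 1], got {self.tumor_fraction}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for e in self.arm_events:
            if e.copy_number < 0:
                raise ValueError("copy numbers must be >= 0")
        for e in self.focal_events:
            if e.copy_number < 0:
                raise ValueError("copy numbers must be >= 0")


@dataclass
class TruthRecord:
    sample_id: str
    tumor_fraction: float
    arm_copy_state: dict[str, int]  # arm name -> copy number (2 = euploid)
    window_copy_state: dict[str, int]  # gene name -> copy number


def simulate_propensities(
    grid: IntervalGrid, efficiency_sd: float = DEFAULT_EFFICIENCY_SD, seed: int = 0
) -> np.ndarray:
    """Per-interval baseline propensities, log-normal around uniform, sum 1.

    Fixed per simulated assay, so panel and test samples share the same
    efficiency landscape.
    """
    if efficiency_sd < 0:
        raise ValueError("efficiency_sd must be >= 0")
    rng = np.random.default_rng(seed)
    p = np.zeros(grid.n_intervals)
    mask = grid.scored
    raw = np.exp(rng.normal(0.0, efficiency_sd, size=int(mask.sum())))
    p[mask] = raw / raw.sum()
    return p


def _copy_number_per_interval(grid: IntervalGrid, cfg: SimulationConfig) -> np.ndarray:
    cn = np.full(grid.n_intervals, 2, dtype=float)
    arm_names = grid.arm_name_per_interval
    for ev in cfg.arm_events:
        sel = arm_names == ev.arm
        if not sel.any():
            raise ValueError(f"unknown arm in event: {ev.arm}")
        cn[sel] = ev.copy_number
    for ev in cfg.focal_events:
        idx = np.asarray(ev.window.member_intervals, dtype=int)
        cn[idx] = ev.copy_number
    return cn


def simulate_sample(
    cfg: SimulationConfig,
    propensities: np.ndarray,
    grid: IntervalGrid,
    sample_id: str = "sim",
) -> tuple[SampleCounts, TruthRecord]:
    """Draw one sample's counts given assay propensities and a config."""
    rng = np.random.default_rng(cfg.seed)
    cn = _copy_number_per_interval(grid, cfg)
    ratio = 1.0 + cfg.tumor_fraction * (cn - 2.0) / 2.0
    w = propensities * ratio
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("degenerate weights: check propensities and events")
    lam = cfg.depth * w / total_w
    if cfg.overdispersion > 0:
        # negative binomial with Var = lam + overdispersion * lam^2
        r = 1.0 / cfg.overdispersion
        counts = rng.negative_binomial(r, r / (r + np.maximum(lam, 1e-12)))
        counts[lam <= 0] = 0
    else:
        counts = rng.poisson(lam)
    truth = TruthRecord(
        sample_id=sample_id,
        tumor_fraction=cfg.tumor_fraction,
        arm_copy_state={
            **{a: 2 for a in grid.arm_names},
            **{e.arm: e.copy_number for e in cfg.arm_events},
        },
        window_copy_state={e.window.gene_name: e.copy_number for e in cfg.focal_events},
    )
    sc = SampleCounts(
        sample_id=sample_id,
        chrom=grid.chrom.copy(),
        start=grid.start.copy(),
        end=grid.end.copy(),
        count=counts.astype(np.int64),
    )
    return sc, truth


def simulate_interval_vector(
    cfg: SimulationConfig, propensities: np.ndarray, grid: IntervalGrid, sample_id: str = "sim"
) -> tuple[IntervalVector, TruthRecord]:
    sc, truth = simulate_sample(cfg, propensities, grid, sample_id)
    return bin_counts(sc, grid), truth


def simulate_euploid_panel(
    grid: IntervalGrid,
    propensities: np.ndarray,
    n_samples: int = 20,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
) -> list[IntervalVector]:
    """Euploid samples sharing one propensity landscape (panel construction input)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_samples):
        cfg = SimulationConfig(seed=int(rng.integers(2**31 - 1)), depth=depth)
        v, _ = simulate_interval_vector(cfg, propensities, grid, sample_id=f"panel{i:03d}")
        out.append(v)
    return out


ANEUPLOID_COPY_CHOICES = (0, 1, 3, 4)


def make_gas_curriculum(
    grid: IntervalGrid,
    propensities: np.ndarray,
    panel,
    n_euploid: int = 100,
    n_aneuploid: int = 100,
    seed: int = 17,
    depth: int = DEFAULT_DEPTH,
    max_events: int = 20,
    n_perm: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Pipeline-computed Z_w feature matrix + labels for GAS training.

    Euploid samples are drawn at tumor fraction 0; aneuploid samples carry
    1..max_events random arm-level gains/losses at tumor fractions
    log-uniform in [0.01, 0.5].  Features are the 39 arm Z_w values computed
    by the full normalization/segmentation pipeline against ``panel``.
    """
    from .panel import pca_normalize
    from .segmentation import score_arms

    if n_euploid < 50 or n_aneuploid < 50:
        raise ValueError("need >= 50 samples per class")
    rng = np.random.default_rng(seed)
    arm_names = list(grid.arm_names)
    feats, labels = [], []
    for i in range(n_euploid + n_aneuploid):
        aneuploid = i >= n_euploid
        events = []
        tf = 0.0
        if aneuploid:
            k = int(rng.integers(1, max_events + 1))
            arms = rng.choice(arm_names, size=min(k, len(arm_names)), replace=False)
            events = [
                ArmEvent(arm=str(a), copy_number=int(rng.choice(ANEUPLOID_COPY_CHOICES)))
                for a in arms
            ]
            tf = float(np.exp(rng.uniform(np.log(0.01), np.log(0.5))))
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31 - 1)),
            depth=depth,
            tumor_fraction=tf,
            arm_events=events,
        )
        v, _ = simulate_interval_vector(cfg, propensities, grid, sample_id=f"cur{i:04d}")
        profile = pca_normalize(v, panel)
        scores = score_arms(profile, grid, n_perm=n_perm, base_seed=seed)
        feats.append(scores.feature_vector())
        labels.append(int(aneuploid))
    return np.asarray(feats), np.asarray(labels, dtype=int)
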