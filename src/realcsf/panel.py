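"""Euploid reference panel: per-interval expectations, PCA denoising basis,
residual scales, and per-gene expected read fractions.

The panel is built from counts of presumed-euploid samples.  Each sample is
depth-normalized to per-interval read proportions over the scored autosomal
intervals.  A PCA basis fitted on the centered panel matrix captures the
correlated technical structure shared across samples (amplicon-efficiency
drift, batch effects); test samples are normalized by subtracting the panel
mean and their projection onto the top-k components, then standardized by
per-interval residual scales.

Residual scales use empirical-Bayes moderation: the raw residual variance of
each interval (with n - 1 - k denominator to account for the mean and the k
removed components) is shrunk halfway toward a mean-variance trend fitted
across intervals.  With small panels the raw per-interval variance has few
effective degrees of freedom and moderation keeps the standardized residuals
close to unit scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .counts import IntervalVector
from .genome import FocalWindow, IntervalGrid

PANEL_SCHEMA_VERSION = 1
DEFAULT_K_COMPONENTS = 5
DEFAULT_MIN_PANEL_SIZE = 10
SIGMA_FLOOR_QUANTILE = 0.05


class PanelError(ValueError):
    """Invalid panel construction or panel/sample mismatch."""


def depth_normalize(v: IntervalVector) -> np.ndarray:
    """Counts over scored intervals as proportions summing to 1.

    Entries for unscored (centromeric / acrocentric-p) intervals are zeroed;
    the result has grid length for positional bookkeeping.
    """
    total = v.total_autosomal_coverage
    if total <= 0:
        raise PanelError(f"{v.sample_id}: zero autosomal coverage")
    p = np.zeros(v.grid.n_intervals, dtype=float)
    sel = v.grid.scored
    p[sel] = v.counts[sel] / total
    return p


@dataclass
class ReferencePanel:
    grid: IntervalGrid
    n_samples: int
    k_components: int
    mu: np.ndarray  # per-interval mean proportion (grid length, zeros off-mask)
    sigma: np.ndarray  # per-interval residual SD (grid length, floored)
    components: np.ndarray  # (k, n_scored) orthonormal loadings on scored intervals
    panel_kind: str = "csf"
    gene_mu: dict[str, float] = field(default_factory=dict)  # μ_gene per registered window

    @property
    def scored_mask(self) -> np.ndarray:
        return self.grid.scored

    def register_window(self, window: FocalWindow) -> float:
        """Precompute μ_gene: the panel-mean fraction of reads in the window."""
        idx = np.array(window.member_intervals, dtype=int)
        mu_gene = float(self.mu[idx].sum()) if len(idx) else 0.0
        self.gene_mu[window.gene_name] = mu_gene
        return mu_gene


def build_reference_panel(
    samples: list[IntervalVector],
    grid: IntervalGrid,
    k_components: int = DEFAULT_K_COMPONENTS,
    min_panel_size: int = DEFAULT_MIN_PANEL_SIZE,
    panel_kind: str = "csf",
    windows: list[FocalWindow] | None = None,
) -> ReferencePanel:
    n = len(samples)
    if n < min_panel_size:
        raise PanelError(f"panel needs >= {min_panel_size} samples, got {n}")
    if k_components >= n:
        raise PanelError(f"k_components ({k_components}) must be < panel size ({n})")
    for s in samples:
        if s.grid is not grid and s.grid.n_intervals != grid.n_intervals:
            raise PanelError(f"{s.sample_id}: grid mismatch")
    mask = grid.scored
    X = np.stack([depth_normalize(s)[mask] for s in samples])  # (n, m)
    mu_scored = X.mean(axis=0)
    Xc = X - mu_scored
    # PCA via SVD of the centered panel matrix
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    components = vt[:k_components]  # (k, m) orthonormal
    resid = Xc - (Xc @ components.T) @ components
    dof = max(n - 1 - k_components, 1)
    s2 = (resid**2).sum(axis=0) / dof
    # mean-variance trend (counts are Poisson-like, so variance ~ mean);
    # 50/50 moderation of per-interval variance toward the trend
    denom = float((mu_scored**2).sum())
    slope = float((s2 * mu_scored).sum() / denom) if denom > 0 else 0.0
    s2_trend = np.maximum(slope * mu_scored, 0.0)
    s2_mod = 0.5 * s2 + 0.5 * s2_trend
    floor = np.quantile(s2_mod[s2_mod > 0], SIGMA_FLOOR_QUANTILE) if np.any(s2_mod > 0) else 0.0
    if floor <= 0:
        raise PanelError("degenerate panel: all residual variances are zero")
    sigma_scored = np.sqrt(np.maximum(s2_mod, floor))

    mu = np.zeros(grid.n_intervals)
    sigma = np.zeros(grid.n_intervals)
    mu[mask] = mu_scored
    sigma[mask] = sigma_scored
    panel = ReferencePanel(
        grid=grid,
        n_samples=n,
        k_components=k_components,
        mu=mu,
        sigma=sigma,
        components=components,
        panel_kind=panel_kind,
    )
    for w in windows or []:
        panel.register_window(w)
    return panel


@dataclass
class NormalizedProfile:
    """Standardized residual profile of one sample against the panel."""

    sample_id: str
    grid: IntervalGrid
    z: np.ndarray  # grid length; finite on retained intervals, 0 elsewhere
    retained: np.ndarray  # bool, grid length
    mask_reason: dict[int, str] = field(default_factory=dict)

    def exclude(self, indices: np.ndarray, reason: str) -> None:
        for i in np.atleast_1d(indices):
            i = int(i)
            if self.retained[i]:
                self.retained[i] = False
                self.mask_reason[i] = reason


def pca_normalize(v: IntervalVector, panel: ReferencePanel) -> NormalizedProfile:
    """Standardized residuals after panel-mean centering and top-k PCA subtraction."""
    if v.grid.n_intervals != panel.grid.n_intervals:
        raise PanelError(f"{v.sample_id}: grid mismatch with panel")
    mask = panel.scored_mask
    p = depth_normalize(v)[mask]
    centered = p - panel.mu[mask]
    proj = (centered @ panel.components.T) @ panel.components
    resid = centered - proj
    z_scored = resid / panel.sigma[mask]
    z = np.zeros(panel.grid.n_intervals)
    z[mask] = z_scored
    return NormalizedProfile(
        sample_id=v.sample_id,
        grid=panel.grid,
        z=z,
        retained=mask.copy(),
    )


def expected_gene_depth(panel: ReferencePanel, window: FocalWindow, coverage: int) -> float:
    """λ_gene = μ_gene × total autosomal coverage of the test sample.

    Raises PanelError when the panel has no reads in the window (μ_gene = 0
    with positive coverage), which makes the gene unscorable.
    """
    idx = np.asarray(window.member_intervals, dtype=int)
    mu_gene = float(panel.mu[idx].sum()) if len(idx) else 0.0
    panel.gene_mu.setdefault(window.gene_name, mu_gene)
    if coverage < 0:
        raise PanelError("coverage must be >= 0")
    if mu_gene <= 0 and coverage > 0:
        raise PanelError(f"{window.gene_name}: no panel coverage in window, not scorable")
    return mu_gene * coverage


# -- serialization -----------------------------------------------------------
# Panels are stored as a single JSON document with embedded float lists.
# Floats round-trip bit-identically via repr (Python emits shortest exact
# decimal); see docs/panel_format.md.


def save_panel(panel: ReferencePanel, path) -> None:
    doc = {
        "schema_version": PANEL_SCHEMA_VERSION,
        "panel_kind": panel.panel_kind,
        "n_samples": panel.n_samples,
        "k_components": panel.k_components,
        "grid": {
            "width": panel.grid.width,
            "chromosomes": [
                {
                    "name": c.name,
                    "length": c.length,
                    "centromere_start": c.centromere_start,
                    "centromere_end": c.centromere_end,
                    "acrocentric": int(c.acrocentric_p_arm),
                }
                for c in panel.grid.layout
            ],
        },
        "mu": panel.mu.tolist(),
        "sigma": panel.sigma.tolist(),
        "components": panel.components.tolist(),
        "gene_mu": panel.gene_mu,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_panel(path) -> ReferencePanel:
    from .genome import Chromosome, GenomeLayout, build_interval_grid

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != PANEL_SCHEMA_VERSION:
        raise PanelError(f"unsupported panel schema: {doc.get('schema_version')}")
    layout = GenomeLayout(
        chromosomes=tuple(
            Chromosome(
                name=c["name"],
                length=c["length"],
                centromere_start=c["centromere_start"],
                centromere_end=c["centromere_end"],
                acrocentric_p_arm=bool(c["acrocentric"]),
            )
            for c in doc["grid"]["chromosomes"]
        )
    )
    grid = build_interval_grid(layout, doc["grid"]["width"])
    panel = ReferencePanel(
        grid=grid,
        n_samples=doc["n_samples"],
        k_components=doc["k_components"],
        mu=np.asarray(doc["mu"], dtype=float),
        sigma=np.asarray(doc["sigma"], dtype=float),
        components=np.asarray(doc["components"], dtype=float),
        panel_kind=doc["panel_kind"],
        gene_mu=dict(doc["gene_mu"]),
    )
    return panel
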