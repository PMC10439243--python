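"""Build a euploid reference panel and normalize a held-out sample.

The panel learns per-interval expectations, a PCA basis for correlated
technical structure, and residual scales. A held-out euploid sample should
normalize to standardized residuals with mean ~0 and SD ~1 — that unit
scale is what makes the downstream arm Z statistics interpretable.
"""

import numpy as np

import realcsf as r

grid = r.build_interval_grid(r.load_default_layout())
prop = r.simulate_propensities(grid, efficiency_sd=0.5, seed=1)

panel_samples = r.simulate_euploid_panel(grid, prop, n_samples=20, depth=1_000_000, seed=3)
panel = r.build_reference_panel(panel_samples, grid, k_components=5,
                                windows=r.load_default_focal_windows(grid))
print(f"panel: {panel.n_samples} euploid samples, k={panel.k_components} PCA components")
print("expected read fraction per focal window:",
      {g: round(m, 5) for g, m in panel.gene_mu.items()})

held_out, _ = r.simulate_interval_vector(
    r.SimulationConfig(seed=4, depth=1_000_000), prop, grid, "held_out")
z = r.pca_normalize(held_out, panel).z[grid.scored]
print(f"held-out euploid residuals: mean {z.mean():+.3f}, SD {z.std():.3f} "
      "(unit scale = calibrated)")
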