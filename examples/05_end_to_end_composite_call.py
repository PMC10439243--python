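"""Full pipeline on two samples: a euploid control and a GBM-like tumor.

The tumor sample combines the chr7-gain / chr10-loss arm pattern with an
8-copy EGFR amplification at 20% tumor fraction. The composite rule is a
Boolean OR: positive if the Global Aneuploidy Score >= 0.25 or any focal
window Z >= 7.5, with the evidence branch recorded on the call.
"""

import realcsf as r

grid = r.build_interval_grid(r.load_default_layout())
windows = r.load_default_focal_windows(grid)
prop = r.simulate_propensities(grid, efficiency_sd=0.5, seed=1)
panel = r.build_reference_panel(
    r.simulate_euploid_panel(grid, prop, 20, depth=1_000_000, seed=3),
    grid, 5, windows=windows)
X, y = r.make_gas_curriculum(grid, prop, panel, 100, 100, seed=17)
model = r.train_gas(X, y, list(grid.arm_names), seed=17)

egfr = next(w for w in windows if w.gene_name == "EGFR")
cases = {
    "control": r.SimulationConfig(seed=8, depth=1_000_000),
    "gbm_like": r.SimulationConfig(
        seed=9, depth=1_000_000, tumor_fraction=0.2,
        arm_events=[r.ArmEvent("chr7p", 3), r.ArmEvent("chr7q", 3),
                    r.ArmEvent("chr10p", 1), r.ArmEvent("chr10q", 1)],
        focal_events=[r.FocalEvent(egfr, 8)],
    ),
}
for name, cfg in cases.items():
    vector, _ = r.simulate_interval_vector(cfg, prop, grid, name)
    call = r.score_sample(vector, panel, model, windows=windows, seed=0)
    arm_calls = [f"{a.arm}:{a.call}" for a in call.arm_scores if a.call != "neutral"]
    focal_pos = [f.gene_name for f in call.focal_scores if f.positive]
    print(f"{name}: {'POSITIVE' if call.positive else 'negative'} "
          f"(evidence={call.evidence}, GAS={call.gas_result.gas:.3f})")
    print(f"  arm calls: {arm_calls or 'none'}; focal: {focal_pos or 'none'}")
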