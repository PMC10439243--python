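"""Simulate an amplicon count profile and aggregate it onto the 500-kb grid.

A simulated assay fixes one per-interval amplification propensity vector
(log-normal heterogeneity, as real repetitive-element amplicons show); a
sample is then a Poisson draw at the requested depth. The printed totals
show conservation through binning and the coverage statistic the focal
test later relies on.
"""

import realcsf as r

layout = r.load_default_layout()
grid = r.build_interval_grid(layout)
print(f"hg19 grid: {grid.n_intervals} bins of {grid.width:,} bp, "
      f"{int(grid.scored.sum())} on the {len(grid.arm_names)} scored arms")

prop = r.simulate_propensities(grid, efficiency_sd=0.5, seed=1)
cfg = r.SimulationConfig(seed=2, depth=1_000_000)
sample, truth = r.simulate_sample(cfg, prop, grid, sample_id="demo")
vector = r.bin_counts(sample, grid)

print(f"requested depth 1,000,000; realized total {vector.counts.sum():,}; "
      f"autosomal coverage {vector.total_autosomal_coverage:,}")
print(f"dropped (off-grid) reads: {vector.dropped}")
# coverage equals the sum over scored intervals: centromeric gaps and
# acrocentric p arms carry no amplicons, so nothing is lost to them
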