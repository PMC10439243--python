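# Methods

`realcsf` detects CNS cancer signal in cerebrospinal-fluid (CSF) or plasma
cell-free DNA from shallow repetitive-element amplicon sequencing. A single
primer pair amplifies a genome-wide family of short interspersed elements,
so each sample is summarized as read counts over genomic intervals; tumor
DNA shifts the count profile wherever the tumor genome carries chromosome
arm gains/losses or focal oncogene amplifications, attenuated by the tumor
fraction of the fluid. The pipeline asks two questions of every sample —
"is the genome-wide arm-level profile aneuploid?" and "is any of four
oncogene windows focally amplified?" — and combines them with a Boolean OR.

## Coordinate model and interval grid

Autosomes only. Coordinates are 0-based half-open (BED convention). Each
chromosome is tiled from position 0 into fixed-width bins (default 500 kb);
a trailing partial bin is dropped so all bins have equal expected counts
and variance. Bins overlapping the centromere gap are flagged `cen` and
excluded from arm assignment. The p arm is `[0, centromere_start)`, the q
arm `[centromere_end, length)`. Acrocentric p arms (chr13/14/15/21/22 on
the bundled hg19 layout) carry no mappable amplicons and are excluded from
the scored set, leaving **39 scored arms**. The bundled hg19 tiling yields
5,754 bins, of which 5,458 belong to scored arms; the production assay's
published grid is slightly smaller because it additionally drops intervals
without amplicon coverage, a filter that depends on the assay rather than
the layout, so the grid here is layout-derived and configurable rather
than pinned to a constant.

Focal windows are gene body ± 1 Mb by default; the shipped four-gene panel
(MDM4 1.5 Mb, CDK4 3.5 Mb, EGFR 1.5 Mb, ERBB2/HER2 2.5 Mb) uses fixed hg19
windows rounded to 100-kb boundaries, which take precedence over the
generic flank rule for those genes.

## Reference panel and normalization

A panel of presumed-euploid samples (minimum 10; 15–20 is typical) defines
the expected profile. Each sample is converted to per-interval read
proportions over the scored intervals (depth normalization, making the
pipeline invariant to total coverage). The panel provides:

- `mu_i` — mean proportion per interval;
- a PCA basis (default k = 5 components) fitted on the centered panel
  matrix, capturing correlated technical structure (amplicon-efficiency
  drift, batch effects) shared across samples;
- `sigma_i` — per-interval residual SD after removing the top-k components.

A test sample is centered by `mu`, its projection onto the k loadings is
subtracted, and the residual is divided by `sigma_i`, giving standardized
residuals `z_i` that are approximately N(0, 1) on euploid data.

**Residual-scale estimation.** With a 15–20 sample panel the per-interval
residual variance has only `n − 1 − k` effective degrees of freedom
(~9–14), and plugging the raw SD into the denominator inflates test-sample
z scores by roughly `sqrt(dof/(dof−2))` ≈ 8–10%. The package therefore (a)
divides residual sums of squares by `n − 1 − k`, and (b) shrinks each
interval's variance 50/50 toward a mean–variance trend fitted across
intervals (variance proportional to `mu_i`, the Poisson-sampling shape) —
the same moderation idea used for small-sample variance estimation in
differential-expression analysis. Variances are floored at the
5th-percentile variance to stop division blow-ups on quiet intervals.
Degenerate panels (all residual variances zero) are rejected.

Choosing k: k must be well below the panel size; k = 5 keeps most of the
panel's degrees of freedom for variance estimation while absorbing the
dominant correlated components. It is a config key.

## Segmentation and arm-level statistics

Each arm's `z_i` sequence is segmented by recursive binary splitting: the
split maximizing the pooled two-sample |t| between left and right parts is
found exhaustively, its significance is assessed by a permutation test
(default 1,000 permutations, α = 0.01, minimum segment width 3 intervals),
and splitting recurses while significant. Permutations are evaluated in
blocks of 100 with early stopping once the p-value is provably above the
gate, so euploid (unsplittable) arms cost ~100 permutations. Permutation
seeds derive deterministically from a CRC of (sample, arm, base seed), so
reruns are byte-identical.

Masking then removes:

- **outliers** — intervals deviating from their segment mean by more than
  4 robust SDs (1.4826 × within-segment MAD);
- **germline CNVs** — segments shorter than 6 intervals (< ~3 Mb) with
  |mean z| > 4: too focal to be an arm-level tumor event. Note that with
  minimum segment width 3, an inherited 1–2 interval CNV is usually caught
  by the outlier rule instead; either path removes it from the arm
  statistic, which is the contract that matters.

All four constants are config keys; the width/magnitude values are this
package's concrete realization of an exclusion step whose thresholds the
assay literature leaves unspecified.

The arm statistic is the Stouffer combination over the m retained
intervals, `Z_w = Σ z_i / √m`, approximately N(0, 1) for a euploid arm
(simulated null: mean ≈ 0.02, SD ≈ 1.05). Arms with fewer than 10 retained
intervals are flagged and contribute a neutral feature value of 0 to the
classifier rather than dropping the sample. Calls: gain if `Z_w > 7.5`,
loss if `Z_w < −7.5`, with a borderline flag for `5 < |Z_w| ≤ 7.5`. At
these thresholds the simulated euploid false-call rate is below 1/39,000
arm tests.

`Z_w` is computed on raw retained intervals rather than segment means;
segmentation serves the masking step. This is a declared design choice —
the upstream aneuploidy-detection literature defers the exact weighting to
its own references — with the null-calibration property (unit scale,
near-zero false calls) as the operative contract.

## Global Aneuploidy Score

An RBF-kernel SVM with the canonical default hyperparameters (C = 1,
gamma = "scale") is trained on the 39 `Z_w` features, clipped to ±50 so
extreme aneuploidy saturates rather than destabilizes kernel distances.
Probability output uses the standard cross-validated Platt calibration; a
sample is GAS-positive at **score ≥ 0.25**. The score grows with both the
number of altered arms and the tumor fraction, saturating near 1 for
clearly aneuploid samples.

The original clinical model was trained on thousands of patient plasma
samples that are controlled-access; this package instead ships a training
*recipe*: a seed-17 curriculum of 100 euploid and 100 aneuploid simulated
samples (1–20 random arm events, tumor fraction log-uniform in
[0.01, 0.5]), with features computed by the full pipeline. Held-out
performance of that recipe in simulation: specificity 1.00 at 0.25 and ROC
AUC ≈ 0.96 (the AUC is limited by aneuploid samples at tumor fractions
near 1%, which are genuinely below the detection floor at 1M reads).
Models serialize to JSON (support vectors, dual coefficients, kernel
width, Platt constants); scoring always goes through the stored arrays, so
a round-trip reproduces scores exactly.

## Focal amplification test

For each gene window, `Observed_gene` is the summed count over the
window's member intervals (or amplicons with midpoints inside the window,
when amplicon-resolution input is given). The panel supplies the expected
read fraction `mu_gene`; with the test sample's total autosomal coverage,
`lambda_gene = mu_gene × Coverage`, and under a Poisson count model

    Z_gene = (Observed_gene − lambda_gene) / sqrt(lambda_gene).

Calling is one-sided (amplifications only) at `Z_gene ≥ 7.5`, mirroring
the arm-level convention; the production assay trained its focal threshold
on cohort data it does not print, so the value here is a config key and a
declared default. Windows with zero panel coverage are reported as
not-scorable rather than erroring. Arm-level aneuploidy under a window is
deliberately not subtracted: `Z_gene` measures total local excess.

## Composite call

`positive = GAS-positive OR any focal-positive`, with an evidence label
(`gas` / `focal` / `both` / `none`). The JSON call record echoes every
threshold so a call is self-describing. Cohort summaries report
sensitivity and specificity with Wilson 95% score intervals.

## Synthetic data model

The simulator is the package's study bench. One simulated "assay" draws a
fixed per-interval propensity vector — log-normal (default log-SD 0.5,
CV ≈ 53%) around uniform, zero on centromeric and acrocentric-p intervals —
shared by the panel and all test samples, emulating heterogeneous amplicon
efficiency. A sample with tumor fraction `tf` and per-interval copy number
`cn_i` has expected weight `propensity_i × (1 + tf·(cn_i − 2)/2)`
(diploid-background mixing), renormalized; counts are Poisson at the
requested depth (default 1e6 reads), or negative binomial
(`Var = λ + φλ²`) when an overdispersion φ > 0 is requested. The default
is pure Poisson so the focal test's null calibration is exact;
overdispersed mode exists to stress-test robustness.

What the simulator does **not** model: GC/mappability structure beyond the
static propensity field, PCR-replicate structure, fragment-length biology,
sequencing error, subclonal heterogeneity, and real inter-patient panel
variation. Passing the simulated suites therefore demonstrates the
statistical machinery is correct and calibrated under the stated count
model — not clinical performance on patient fluids.

## Problem sizes, determinism, numerical notes

- Null-calibration suites use 500–1,000 simulated euploid samples against
  a 20-sample panel at depth 1e6 on the full hg19 grid; dose-response uses
  50 samples per tumor-fraction level {0, 0.01, 0.03, 0.1, 0.3} with a
  fixed five-arm event profile. These sizes give binomial CIs narrow
  enough for the properties asserted while keeping a laptop run in minutes.
- Every stochastic step takes an explicit seed; per-(sample, arm) CBS seeds
  derive from a CRC so sample order is irrelevant.
- The dose-response monotonicity diagnostic in the acceptance script
  treats decreases smaller than 1e−3 as ties: below that resolution,
  adjacent tumor-fraction levels are statistically indistinguishable at 50
  samples per level and the sign of the difference is sampling noise.
- The step-recovery diagnostic asserts breakpoint localization (±2
  intervals); demanding exactly two segments in every replicate would
  contradict the segmenter's own α = 0.01 split gate (~2% spurious splits).
- Wilson intervals come from statsmodels; at k = n the upper bound is 1
  only to float precision (1 − 1e−16).
- Tie-breaks: argmax over split points takes the first index; masking is
  applied per segment in arm order; duplicate-coordinate count records are
  summed with a warning.

## Known limitations

- No GC-content or mappability correction; the PCA panel absorbs static
  bias shared with the panel, nothing sample-specific.
- Focal deletions are reported as negative `Z_gene` but never gate a call.
- Tumor fraction is not estimated; evidence stays on the Z scale.
- Arms shorter than the retained-interval minimum are neutral features, a
  conservative choice that slightly discounts genuinely aneuploid samples
  with heavy masking.
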