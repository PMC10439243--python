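# realcsf

Copy-number–based detection of CNS cancer from shallow repetitive-element
amplicon sequencing of cerebrospinal-fluid (CSF) or plasma cell-free DNA.

A single primer pair amplifies a genome-wide family of repetitive elements,
turning a few nanograms of fluid DNA into per-interval read counts. Tumor
DNA shifts that count profile wherever the tumor genome carries chromosome
arm-level gains/losses (aneuploidy) or focal oncogene amplifications,
diluted by the tumor fraction of the fluid. `realcsf` implements the full
calling pipeline plus a synthetic-data simulator, so every stage can be
exercised, calibrated and trained without patient data. It is aimed at
computational-biology groups working on liquid-biopsy copy-number analysis.

## Method

1. **Binning** — aligned read counts are aggregated onto non-overlapping
   500-kb autosomal intervals (the bundled hg19 layout yields 5,754 bins,
   5,458 of them on the 39 non-acrocentric autosomal arms that are scored).
2. **Reference-panel normalization** — each sample becomes per-interval
   read proportions; a panel of euploid samples supplies the expected
   proportion μᵢ, a PCA basis (top k = 5 components) for correlated
   technical structure, and moderated residual scales σᵢ. A test sample's
   standardized residual is zᵢ = (pᵢ − μᵢ − PCA projection)/σᵢ ≈ N(0, 1)
   on euploid data.
3. **Segmentation and arm statistics** — each arm is segmented by
   binary-split circular binary segmentation (exhaustive max-|t| splits,
   permutation-gated at α = 0.01); germline-like short events and outliers
   are masked; the arm statistic is the Stouffer combination
   **Z_w = Σzᵢ/√m** over the m retained intervals. Gains call at
   Z_w > 7.5, losses at Z_w < −7.5 (borderline band 5 < |Z_w| ≤ 7.5).
4. **Global Aneuploidy Score (GAS)** — an RBF-kernel SVM over the 39 Z_w
   features emits a calibrated probability of aneuploidy; positive at
   **GAS ≥ 0.25**. The package ships a training recipe on simulated
   curricula (the original clinical training cohort is controlled-access).
5. **Focal amplification** — for each of four oncogene windows (MDM4,
   CDK4, EGFR, ERBB2/HER2), observed window counts are tested against the
   panel expectation λ_gene = μ_gene × Coverage with a Poisson Z:
   **Z_gene = (Observed_gene − λ_gene)/√λ_gene**, one-sided positive at
   Z_gene ≥ 7.5.
6. **Composite call** — Boolean OR: a sample is positive if the GAS gate
   or any focal gate fires, with the evidence branch recorded.

Details, parameter defaults and limitations: [docs/methods.md](docs/methods.md).
Panel file format: [docs/panel_format.md](docs/panel_format.md).

## Worked example

`examples/05_end_to_end_composite_call.py` simulates an assay (heterogeneous
amplicon efficiencies, 20-sample euploid panel at 1M reads), trains the GAS
on the default seed-17 curriculum, and scores two samples — a euploid
control and a glioblastoma-like sample (chr7 gain, chr10 loss, 8-copy EGFR
amplification, 20% tumor fraction):

```
control: negative (evidence=none, GAS=0.000)
  arm calls: none; focal: none
gbm_like: POSITIVE (evidence=both, GAS=0.638)
  arm calls: ['chr7p:gain', 'chr7q:gain', 'chr10p:loss', 'chr10q:loss']; focal: ['EGFR']
```

The control stays at GAS ≈ 0 with no arm or focal calls; the tumor sample
crosses both gates — all four engineered arm events are recovered at
|Z_w| > 7.5 and the EGFR window is amplification-positive — so the
composite evidence is `both`. The arm-level view
(`examples/03_arm_segmentation_and_zw.py`) of the same event profile:

```
arm    Z_w      call
chr7p   +14.23  gain
chr7q   +18.50  gain
chr10p  -13.42  loss
chr10q  -17.20  loss
... and 35 unremarkable arms (|Z_w| <= 5)
```

and the focal panel on an EGFR-amplified sample
(`examples/04_gas_training_and_focal.py`):

```
MDM4   observed    799  lambda    780.4  Z   +0.67  negative
CDK4   observed   1405  lambda   1404.0  Z   +0.03  negative
EGFR   observed   1276  lambda    781.4  Z  +17.69  POSITIVE
ERBB2  observed    716  lambda    743.3  Z   -1.00  negative
```

Each example script in `examples/` is self-contained and prints what the
numbers mean; 01–02 cover simulation/binning and panel normalization.

## Command line

The same pipeline is scriptable from a shell:

```bash
realcsf simulate    --n-euploid 15 --seed 5 --out-dir panel_counts/
realcsf build-panel --counts-dir panel_counts/ --k 5 --out panel.rcsf
realcsf train-gas   --features F.tsv --labels L.tsv --seed 17 --out gas.model
realcsf score       --panel panel.rcsf --model gas.model --counts sample.tsv --out-prefix out/sample
realcsf summarize   --calls out/ --truth truth.json
```

`score` writes an arm TSV, a focal TSV and a self-describing JSON call
record (all thresholds echoed). Exit code 2 signals a validation error.

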