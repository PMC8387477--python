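# radstab

Stability analysis of radiomic features across paired fast/conventional MRI
acquisitions, exercised end-to-end on synthetic paired-acquisition cohorts.

The package provides:

- **Imaging I/O and mask algebra** (`radstab.imaging`): NIfTI volumes and
  binary ROI masks, nearest-neighbour mask resampling between grids,
  whole vs intersection ROI masks, and enumeration of the 14 mask roles of
  a two-group paired design (3 whole + 4 intersection roles per group).
- **Synthetic cohorts** (`radstab.synthetic`): textured hyperintense-lesion
  phantoms, acquisition-degradation profiles (matrix down-sampling after the
  protocol ratios 256×218 / 128×128 / 192×192 / 256×256, in-plane blur,
  additive noise, imperfect mask transfer), bivariate-normal feature-pair
  simulation with a known population concordance, and a one-command demo
  cohort writer.
- **Feature extraction** (`radstab.discretize`, `radstab.features`,
  `radstab.wavelet`): a fixed 595-entry catalog — 46 first-order features,
  61 spatial-domain texture features (5 second-order, 22 GLCM, 11 GLRLM,
  5 LBP, 13 GLSZM, 5 NGTDM) and 488 wavelet features (the same 61 texture
  features on each of 8 undecimated 2-level Haar subbands). Texture
  matrices are built per slice with distance-1 in-plane offsets and pooled
  across slices/directions; gray levels use fixed-bin-number discretization
  (Ng = 32 default). Degenerate statistics are reported as NaN, never 0.
- **Stability analysis** (`radstab.stability`): Lin's concordance
  correlation coefficient per feature, stability at CCC > 0.85 (strict),
  per-stratum summaries (proportion stable out of 595, median CCC with a
  seeded percentile-bootstrap 95% CI, per-family stable counts), and
  McNemar comparison of the two fast sequences' stability indicators
  (exact binomial below 25 discordant pairs, continuity-corrected χ²
  above).

## CLI

```sh
# 1. generate a synthetic two-group paired cohort (NIfTI + manifest.csv)
radstab simulate --n-per-group 6 --seed 1 --outdir scratch/cohort

# 2. extract the 595-feature catalog for every mask role
radstab extract --manifest scratch/cohort/manifest.csv --out scratch/features.csv

# 3. per-feature CCC, stability table, McNemar tests, heatmap matrix
radstab analyze --features scratch/features.csv --outdir scratch/report

# inspect the feature registry
radstab catalog --out scratch/catalog.csv
```

`analyze` writes `stability_summary.csv` (one row per group × lesion class
× mask kind × fast sequence), `mcnemar.csv`, `ccc_matrix.csv`
(features × strata, blank cells for undefined CCCs) and an optional
`ccc_heatmap.png`. Every CSV embeds the catalog hash and the full config
in its header line. A YAML config (`--config`) can override
`discretization.ng`, `wavelet.family`, `stability.threshold`,
`bootstrap.reps` and `bootstrap.seed`.

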