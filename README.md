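# phenoniche

Phenotype-stratified niche modelling and spatial statistics for polymorphic
coat-colour phenotypes (melanistic vs. non-melanistic), runnable end-to-end on
synthetic landscapes with known ground truth.

The package implements:

- **`phenoniche.synth`** — synthetic landscape generator: spatially
  autocorrelated environmental layers with an exactly imposed cross-correlation
  structure, categorical biome maps, a vegetation-change layer, and
  phenotype-labelled presence records sampled from configurable per-phenotype
  suitability surfaces.
- **`phenoniche.records`** — record I/O and validation, camera-trap
  deduplication within a 25 km buffer diameter, and the three-rule filter
  (age ≥ 20 years, exact coordinate duplicates, |vegetation-index change| ≥ 0.7)
  with a fully reconciled removal report.
- **`phenoniche.association`** — biome × phenotype contingency table with
  expected counts, three percentage blocks, adjusted standardized residuals,
  Pearson chi-square, likelihood-ratio G, and a linear-by-linear trend
  statistic with configurable ordinal scores.
- **`phenoniche.csr`** — complete-spatial-randomness test against an
  inhomogeneous null: buffer-union study polygon, Gaussian-kernel intensity
  estimate, nearest-neighbour G-function and a Kolmogorov-type Monte Carlo
  deviation test.
- **`phenoniche.maxent`** — from-scratch maximum-entropy presence-background
  model: linear/quadratic/product/hinge features standardized to [0, 1],
  sample-size-dependent L1 regularization, monotone proximal-gradient
  optimization, logistic output, replicated 70/30 evaluation with
  rank-based AUC, permutation variable importance and response curves, plus
  Pearson-correlation predictor pre-selection at a 0.7 cutoff.
- **`phenoniche.overlap`** — niche-overlap statistics (Schoener's D,
  Hellinger-based I, relative rank computed exactly via a discordant-pair
  identity), the resampling niche-equivalency test, and the paired
  suitability t-test.
- **`phenoniche.env_effects`** — per-scale environmental-driver contrasts with
  Bonferroni correction, suitability~variable regressions, a latitudinal
  barrier contrast on equal point counts per side, and leave-region-out
  robustness refits.
- **`phenoniche.pipeline` / `phenoniche.cli`** — end-to-end orchestration with
  per-stage seeds derived deterministically from one global seed.

All rasters are plain numpy grids with ESRI ASCII grid (`.asc`) text I/O;
records are CSV; reports are JSON.

## CLI

```bash
phenoniche synth --seed 7 --n-records 600 --out run/synthetic
phenoniche records run/synthetic/records.csv \
    --ndvi-change run/synthetic/ndvi_change.asc --cutoff 0.7 --max-age 20 \
    --out run/filtered.csv
phenoniche assoc run/filtered.csv --biomes run/synthetic/biomes.asc --out-prefix run/assoc
phenoniche csr run/filtered.csv --phenotype melanistic --nsim 500 --seed 7 --out run/csr.json
phenoniche sdm run/filtered.csv --env-dir run/synthetic/env --phenotype melanistic \
    --replicates 10 --seed 7 --out-prefix run/mel
phenoniche compare --model-a run/mel_suitability.asc --model-b run/non_suitability.asc \
    --out run/overlap.json
phenoniche all --synthetic --seed 7 --out run/full   # whole pipeline in one go
```

`phenoniche all` writes every stage artifact plus `manifest.json`; two runs
with the same seed produce byte-identical manifests.

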