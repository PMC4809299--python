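# namqtl

Simulation and analysis toolkit for nested association mapping (NAM)
populations of backcross–selfing (BC1S3) lines: multi-year phenotype
aggregation, multi-family GWAS with cofactor selection, and resampling-based
QTL detection with predictive-ability estimation.

## What it does

* **`namqtl.simulate`** — synthetic NAM populations: genetic maps,
  BC1S3 families (Haldane meioses, no interference), per-family
  polymorphism masks, additive (optionally family-specific) QTL models,
  multi-year/replicate phenotypes with genotype, genotype×year and residual
  variance, and daily temperature series.
* **`namqtl.pheno`** — growing degree days (base 0 °C), variance components
  (exact ANOVA estimator for balanced designs, dense REML otherwise),
  broad-sense heritability `h² = V_G / (V_G + V_GY/y + V_R/(y·r))`, per-line
  BLUEs (genotype fixed; year and genotype×year random, solved through
  sparse mixed-model equations when unbalanced), descriptive statistics and
  Pearson trait correlations.
* **`namqtl.gwas`** — the association scan: intercept + family + SBC-selected
  cofactors + marker dosage, with strict `< 1 cM` same-chromosome cofactor
  exclusion, Bonferroni–Holm adjustment, single-marker R² and family-nested
  marker effects.
* **`namqtl.cv`** — family-stratified 80 % subsampling, detection rates,
  QTL consolidation (`< 4 cM` chaining, ≥ 10 % detection), Ezekiel adjusted
  R², hold-out predictive ability and the multi-trait QTL summary table.
* **`namqtl.io` / `namqtl.cli`** — plain-text TSV/CSV formats and the
  `namqtl` command-line pipeline.

## Command-line pipeline

```bash
namqtl simulate --out demo --seed 7 --families 5 --lines 40
namqtl blues    --out demo --seed 7
namqtl gwas     --out demo --seed 7
namqtl cv       --out demo --seed 7
namqtl report   --out demo --seed 7
```

Stages can also be configured through a YAML file (`--config config.yaml`)
whose keys mirror `namqtl.cli.PipelineConfig` (defaults: α = 0.05, 1 cM
exclusion, 200 runs, 80 % fraction, 10 % detection threshold, 4 cM merge).
Outputs carry `#` header lines with the package version, a config hash and
the base seed; identical config + seed reproduces files byte-for-byte.

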