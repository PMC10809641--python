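# epiclock

Methylation-based skin-aging clocks, end to end: synthetic cohort
generation, probe QC + quantile normalization, low-methylated-region (LMR)
calling from WGBS-like counts, ridge-regression clock training for three
aging outcomes (wrinkle grade, visual facial age, visual age progression),
validation statistics, and a three-arm gene-ranking + preranked-enrichment
consensus for pathway interpretation.

Real cohort data for this kind of analysis is typically access-restricted,
so the package ships a first-class simulator (`epiclock.synth`) that plants
LMRs, progression-linked and age-linked CpGs, multi-rater phenotype noise,
WGBS counts and progression-correlated expression — every downstream stage
is fully testable offline with known ground truth.

## Layout

| module | purpose |
| --- | --- |
| `epiclock.synth` | synthetic cohorts: beta matrices with planted signal, panel ratings, WGBS counts, expression |
| `epiclock.preprocess` | detection-p / blocklist probe filtering, full quantile normalization, CpG→LMR averaging |
| `epiclock.lmr` | smoothing, cutoff segmentation into LMR/UMR, permutation-based FDR calibration, probe intersection |
| `epiclock.clock` | stratified 80/20 partition, ridge fit (alpha=0), 100-step lambda path, 10-fold CV selection by MAE |
| `epiclock.evaluate` | MAE, Pearson r + t-test, exact/approximate Wilcoxon rank-sum, clock validation reports |
| `epiclock.enrich` | coefficient-sum and correlation-average gene rankings, weighted-KS enrichment with permutation NES/p, cross-source consensus |
| `epiclock.pipeline` / `epiclock.cli` | config-driven orchestration with per-stage seeds and provenance |

## CLI

Each stage is a subcommand sharing one output directory; `run-all` executes
the whole flow. Configuration is YAML (see `configs/demo.yaml`; omitted keys
fall back to defaults in `epiclock.pipeline.DEFAULT_CONFIG`).

```bash
epiclock run-all --config configs/demo.yaml --outdir out/
epiclock simulate --config configs/demo.yaml --outdir out/
epiclock predict --model out/train/model_progression_lmr.json \
    --beta out/lmr/beta_lmr.tsv --out out/predictions.tsv
epiclock evaluate-model --model out/train/model_progression_lmr.json \
    --beta out/lmr/beta_lmr.tsv --phenotypes out/simulate/phenotypes.tsv
```

Outputs are plain text (TSV / BED / GMT / RNK / JSON). Identical configs
produce byte-identical outputs; `run_manifest.json` records the config hash,
seed and per-file checksums. Exit codes distinguish configuration (2),
data (3), model (4), calibration (5) and ranking (6) errors.

## Conventions

- Beta values are methylation fractions in [0, 1]; matrices are features x
  samples TSVs.
- Internal coordinates are 0-based half-open; probe-manifest TSVs are
  1-based on disk (array convention) and converted on ingest; BED and WGBS
  tables are 0-based natively.
- Ridge coefficients solve `(X'X + lambda * n * I) b = X'(y - ybar)` on
  features standardized to population SD 1; the intercept is unpenalized.
- Enrichment normalizes ES by the mean |null ES| of matching sign over
  gene-label permutations; nominal p uses the plus-one estimator.
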