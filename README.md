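# roscore

Points-based gene-expression survival scoring for right-censored cohorts.

The pipeline has three stages:

1. **Screening** — every candidate gene splits the cohort at its median
   expression; the high-vs-low survival difference is tested with the
   log-rank test, and the direction of effect (is above-median expression
   favorable?) is read off the univariate Cox hazard ratio. Genes with
   log-rank P < 0.15 (strict, no multiplicity correction) form the panel,
   ordered by ascending P.
2. **Scoring** — each patient earns one point per panel gene whose
   expression lies on that gene's favorable side of the cohort median
   (strictly above for `high_good` genes, at-or-below for `low_good`).
   Scores run 0..K; the equal-range split labels scores > K/2 "high"
   (for the packaged 25-gene panel: low = 0–12, high = 13–25).
3. **Evaluation** — Kaplan–Meier curves and log-rank test by group,
   univariate and multivariable Cox regression (score as category or as
   integer points, alongside age / grade / stage / residual disease),
   the score-vs-median-OS Pearson correlation, subgroup analyses, and a
   survival-threshold ROC comparison of clinical covariates, the score,
   and both combined.

All survival statistics (Kaplan–Meier with Greenwood variance, log-rank,
Cox by Newton–Raphson with Efron/Breslow ties, Mann–Whitney AUC) are
implemented from scratch in `roscore.survival` and cross-checked in the
test suite against independent oracles plus `lifelines` / `scikit-learn`.

A synthetic-cohort generator (`roscore.simulate`) plants median-group
hazard effects with known ground truth, so every stage is testable without
external data. Presets `tcga_like` (511 patients × 179 genes),
`tothill_like` (240) and `tj_like` (105 × 25) mirror the cohort shapes the
method is usually applied to.

Because scoring only looks at each gene's rank relative to the cohort
median, any monotone per-gene expression scale works unchanged: microarray
intensities, log counts, or qPCR −ΔCt values.

## CLI

```sh
# simulate a cohort with known truth
roscore simulate --preset tcga_like --seed 1 --out runs/sim

# discovery: screen -> panel -> scores -> evaluation bundle
roscore discover --expression runs/sim/expression.tsv \
                 --clinical runs/sim/clinical.tsv --out runs/disc

# validation: score a cohort against a frozen panel
# (builtin panel name "table1" = the packaged 25-gene panel, or a TSV path)
roscore validate --expression expr.tsv --clinical clin.tsv \
                 --panel table1 --out runs/val
```

Each subcommand also accepts `--config FILE` (YAML; flags override config
keys — see `RunConfig` keys in `roscore/cli.py`). Every run writes a
`manifest.json` with the resolved config, package version and input
checksums, TSV result tables, a JSON report, and KM / forest / ROC /
scatter plots.

Expression input is a genes-in-rows TSV/CSV (first column gene symbol,
header sample ids, `NA` for missing). Clinical input is one row per sample
with configurable header mapping onto `sample_id`, `os_years`, `os_event`,
`age`, `stage`, `grade`, `residual_mm`; residual disease is recoded
optimal (≤ 10 mm) / suboptimal at read time. Extra columns pass through as
strata for subgroup analyses.

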