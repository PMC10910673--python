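# mrscreen

Two-sample Mendelian randomization (MR) screening of GWAS summary
statistics: given per-variant association tables for a quantitative
exposure (e.g. a plasma metabolite, SD units) and a binary outcome (e.g. a
cancer, log-odds), the package selects genetic instruments, estimates the
causal effect with four estimators, runs pleiotropy/heterogeneity/
directionality diagnostics, and condenses the evidence into a six-criterion
confidence ledger. A seeded synthetic-GWAS generator makes every stage
testable at desk scale.

## What's inside

| module | role |
|---|---|
| `mrscreen.sumstats` | read/validate summary-statistic tables; allele harmonization (palindrome removal, swap/strand-flip resolution, orientation to non-negative exposure effects) |
| `mrscreen.instruments` | MAF filter, greedy LD clumping (p-ordered, windowed, r² threshold), per-instrument R²/F statistics, weak-instrument and Steiger directionality filters |
| `mrscreen.estimators` | Wald ratio, IVW (fixed / multiplicative-random), weighted median (bootstrap SE), Egger regression, Cochran's Q, leave-one-out |
| `mrscreen.presso` | simulation-based residual-sum-of-squares pleiotropy testing: global test, per-instrument outlier test (Bonferroni), outlier-corrected estimate, distortion test |
| `mrscreen.mvmr` | multivariable IVW direct effects over union instrument sets + conditional instrument strength |
| `mrscreen.coloc` | Wakefield approximate-Bayes-factor colocalization over the five locus hypotheses (PP0–PP4) |
| `mrscreen.screening` | Bonferroni flags, binary-outcome power, the confidence ledger, reverse MR, replication concordance, end-to-end `screen_pair` |
| `mrscreen.simulate` | paired synthetic exposure/outcome GWAS with known truth: pleiotropy (balanced/directional), outliers, reverse causation, LD blocks, regional stats for colocalization, named scenario presets |
| `mrscreen.ivtable` | loader for published instrument-level association tables (reproduces reported odds ratios) |

## CLI

Every stage is exposed as a subcommand; global flags `--config <yaml>`,
`--seed`, `--out-dir`, `--log-level` come first:

```bash
mrscreen --seed 7 --out-dir sim       simulate --preset causal
mrscreen --seed 7 --out-dir sel       select --exposure sim/exposure.tsv \
         --outcome sim/outcome.tsv --ld-panel sim/ld_panel.tsv
mrscreen --seed 7 --out-dir mr        mr --ivs sel/instruments.tsv
mrscreen --seed 7 --out-dir presso    presso --ivs sel/instruments.tsv
mrscreen --seed 7 --out-dir screen    screen --exposure sim/exposure.tsv \
         --outcome sim/outcome.tsv --ld-panel sim/ld_panel.tsv --bonferroni-m 500
mrscreen --out-dir rep                report --iv-table data/published_iv_table.tsv
```

`simulate` presets: `null`, `causal`, `balanced_pleiotropy`,
`directional_pleiotropy`, `outliers`, `weak_instruments`, `reverse_causal`,
`two_cohort_replication`.

Thresholds (clumping p/r²/window, MAF, F, n_sim, colocalization priors,
Bonferroni denominators) live in a YAML config; see
`mrscreen.config.RunConfig` for the schema.

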