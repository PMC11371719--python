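# tsmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection, effect-allele harmonization, IVW / MR-Egger /
weighted-median causal estimation, sensitivity diagnostics (Cochran's Q,
Egger intercept, leave-one-out, simulation-based residual-sum outlier
testing), forward + reverse pipeline orchestration, and a synthetic
summary-statistic generator with known ground truth.

## Layout

| Module | Purpose |
|---|---|
| `tsmr.summary_stats` | Data model, TSV/CSV readers/writers, row-level validation |
| `tsmr.instruments`   | p-value filter, greedy LD clumping, confounder exclusion list, F-statistic weak-instrument screen |
| `tsmr.harmonize`     | Common-effect-allele alignment, strand complements, frequency-based palindrome resolution, per-SNP audit |
| `tsmr.estimators`    | Wald ratio, IVW (fixed / multiplicative random effects), MR-Egger, interpolated weighted median, odds-ratio reporting |
| `tsmr.sensitivity`   | Cochran's Q, Egger-intercept pleiotropy test, leave-one-out series, residual-sum outlier procedure (global / outlier / distortion tests, corrected IVW) |
| `tsmr.pipeline`      | YAML-configured forward + reverse runs, per-pair error isolation, report exports with `/` sentinels, run manifest |
| `tsmr.synthetic`     | Exposure/outcome pair simulator (pleiotropy regimes, outliers, palindromic alleles) and block LD matrices |

## CLI

All verbs read one YAML run configuration:

```sh
tsmr simulate    -c config.yaml   # write synthetic exposure/outcome TSVs + truth
tsmr select      -c config.yaml   # instrument selection per exposure
tsmr harmonize   -c config.yaml   # selection + harmonization audits
tsmr estimate    -c config.yaml   # + IVW / MR-Egger / weighted median
tsmr sensitivity -c config.yaml   # + heterogeneity / pleiotropy / outlier tests
tsmr run         -c config.yaml   # full forward + reverse pipeline, all exports
```

Minimal configuration:

```yaml
seed: 1
output_dir: out
exposures:
  - name: taxonA
    path: data/exposure.tsv
    meta: {trait_type: continuous, n_total: 18340}
outcomes:
  - name: disease
    path: data/outcome.tsv
    meta: {trait_type: binary, n_total: 213353, n_cases: 208, n_controls: 213145}
thresholds:            # all optional; defaults shown
  iv_pval: 1.0e-5
  reverse_iv_pval: 1.0e-5
  ld_r2: 0.001
  clump_window_kb: 10000
  f_threshold: 10
  palindrome_eaf_limit: 0.42
estimators:
  ivw_model: multiplicative_random
  n_boot: 1000
  presso_n_sim: 1000
  outlier_alpha: 0.05
# ld_matrix: data/ld.tsv          # optional square r2 matrix with ID headers
# exclusion_list: data/excl.tsv   # optional: snp_id [tab reason] per line
```

Summary-statistic files are delimited text with canonical columns
`SNP, effect_allele, other_allele, eaf, beta, se, pval, n` (`NA` for a
missing frequency); a per-dataset `column_map` adapts foreign headers.
Outputs are tab-delimited report tables (`estimates.tsv`,
`sensitivity.tsv`, `leave_one_out.tsv`, `presso.tsv`, per-pair
harmonization audits and scatter data) plus a `manifest.yaml` capturing the
full configuration and seed; runs are byte-for-byte reproducible under the
same seed. Methods that cannot be computed at the available instrument
count are reported with `/` sentinels.

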