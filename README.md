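# tsmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection and LD clumping, proxy substitution, allele
harmonization, four causal estimators (IVW, weighted median, weighted mode,
MR-Egger), heterogeneity/pleiotropy diagnostics including a resampling
outlier test (global / per-SNP / distortion), leave-one-out analysis, and
binary-outcome power calculation — plus a synthetic summary-statistics
generator with known ground truth so the whole pipeline is testable offline.

## Package layout

| module             | what it does |
|--------------------|--------------|
| `tsmr.gwas_io`     | read/write/validate summary-stats tables (TSV/CSV, dialect presets incl. COVID-19 HGI r5) and pairwise LD files |
| `tsmr.instruments` | p-value-ranked greedy LD clumping, proxy lookup, allele harmonization (swaps, strand flips, palindrome filtering), per-SNP R² and F statistics |
| `tsmr.estimators`  | Wald ratios, IVW (multiplicative random effects), MR-Egger, weighted median, weighted mode (bootstrap SEs, seeded) |
| `tsmr.diagnostics` | Cochran Q, Egger intercept test, resampling RSS outlier test, leave-one-out, scatter/funnel/forest plot tables |
| `tsmr.power`       | binary-outcome MR power and smallest detectable OR (closed-form inversion) |
| `tsmr.simulate`    | synthetic two-sample GWAS generator + named fixture presets |
| `tsmr.pipeline`    | YAML-config-driven end-to-end analysis with provenance audit |
| `tsmr.cli`         | `tsmr run / simulate / power / validate` |

## CLI

```bash
# write a synthetic fixture (exposure/outcome/LD/truth TSVs)
tsmr simulate --preset asthma_susceptibility --seed 1 --out fixtures/

# run the full analysis from a config file
tsmr run --config analysis.yaml

# power: smallest detectable OR at 80% power, and power at a given OR
tsmr power --cases 38984 --controls 1644784 --r2 0.0235 --or 1.1

# validate a summary-statistics file
tsmr validate --path fixtures/asthma_susceptibility.exposure.tsv
```

A minimal `analysis.yaml`:

```yaml
exposure: {label: asthma, path: fixtures/asthma_susceptibility.exposure.tsv}
outcomes:
  - {label: covid, path: fixtures/asthma_susceptibility.outcome.tsv}
ld_path: fixtures/asthma_susceptibility.ld.tsv
seed: 1
out_dir: results/
```

Outputs: `estimates.tsv`, `diagnostics.tsv`, `outliers.tsv`, `loo.tsv`,
`provenance.tsv`, `power.tsv`, per-outcome scatter/funnel/forest/lines
tables, and a deterministic `run.log`. If the outlier test flags variants,
an outlier-removed IVW row is appended automatically.

## File formats

Summary statistics: delimited text with header
`variant_id effect_allele other_allele eaf beta se pval n_total [n_cases n_controls]`
(TSV by default; CSV accepted; `NA` for missing; floats round-trip
bit-identically). LD: three columns `id1 id2 r2`; the mapping is symmetric,
absent pairs count as r² = 0.
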