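# perimr

One-sample Mendelian randomization (MR) from GWAS summary statistics, built
around the question of whether perinatal factors — birth weight, maternal
smoking in pregnancy, breastfeeding — causally influence amblyopia risk.
The package is a complete, tested summary-data MR pipeline for
epidemiologists: instrument selection with LD clumping, allele
harmonization, four pooled causal estimators, pleiotropy and heterogeneity
diagnostics, and binary-outcome statistical power. A bundled synthetic
summary-statistics generator with known ground truth makes every stage
verifiable end-to-end without any data download.

## The method

Each genetic instrument j contributes a Wald ratio

```
θ̂_j = β_Yj / β_Xj ,      se(θ̂_j) = σ_Yj / |β_Xj|
```

where (β_Xj, σ_Xj) is the SNP–exposure association and (β_Yj, σ_Yj) the
SNP–outcome association (log-odds for a binary outcome). The pooled
estimators are:

- **IVW (fixed effects)** — θ̂ = Σ w_j θ̂_j / Σ w_j with w_j = 1/se(θ̂_j)²,
  SE = (Σ w_j)^(-1/2); identical to weighted least squares of β_Y on β_X
  through the origin.
- **IVW (multiplicative random effects)** — same point estimate, SE scaled
  by √(Q/(J−1)) with Q = Cochran's Q about the IVW estimate. The scale is
  *not* floored at 1, so an underdispersed instrument set reports a
  random-effects SE below the fixed-effects SE (a `floor_dispersion` flag
  restores the floored convention).
- **Simple / weighted median** — the 50% point of the cumulative-weight
  distribution over ordered ratios (equal or inverse-variance weights),
  robust when up to half of the instruments (or half of the weight) is
  invalid; SE by parametric bootstrap.
- **MR-Egger** — weighted regression of β_Y on β_X with a free intercept;
  the intercept estimates directional pleiotropy, the slope is a
  pleiotropy-robust causal estimate.

Diagnostics: Cochran's Q about the IVW estimate (χ², J−1 df), Egger
residual Q (J−2 df), Egger intercept z-test, and per-instrument
F-statistics (β/σ)². Estimates on the log-odds scale are reported with
OR = exp(β) and Wald confidence intervals. Statistical power for a binary
outcome follows the mRnd non-centrality calculation.

## Worked example

Run the full pipeline on synthetic data generated at the scale of the
amblyopia study (exposure GWAS N = 262,966; binary outcome 862 cases /
416,168 controls; 18 true instruments among 118 SNPs; true causal effect
θ = −0.73):

```yaml
# config.yaml
out_dir: out
seed: 42
simulate:
  n_instruments: 18
  n_null_snps: 100
  theta: -0.73
  tau: 0.05
mr:
  n_boot: 1000
power:
  r_squared: 0.053
```

```
$ perimr run --config config.yaml
report -> out/report.json
ivw_random: beta=-0.6254 se=0.2441 p=0.0104
ivw_fixed: beta=-0.6254 se=0.4285 p=0.1444
simple_median: beta=-0.7756 se=0.6347 p=0.2217
weighted_median: beta=-0.8263 se=0.5346 p=0.1222
egger_slope: beta=-1.09 se=0.5286 p=0.03918
power = 0.8816
```

Reading the output: of 118 input variants, 11 survive the p < 1e-6
significance filter and LD clumping, all 11 harmonize against the outcome
table, and every estimator recovers a negative causal effect bracketing
the simulated θ = −0.73. The run's Q statistics (Q/df ≈ 0.32, p ≈ 0.98)
show an *underdispersed* instrument set, so the unfloored random-effects
SE (0.244) is smaller than the fixed-effects SE (0.429) — the same pattern
the real birth-weight analysis exhibits. The final power line re-evaluates
the study's detectability given the estimated odds ratio.

The stages are also available separately (`perimr simulate | select |
harmonize | mr | power`), each reading and writing plain TSV/JSON, e.g.

```
$ perimr power --n 417030 --cases 862 --controls 416168 --or 0.48 --r2 0.053
power = 0.9401 (ncp = 3.516)
```

— the study-level power of the published birth-weight analysis (94%).

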