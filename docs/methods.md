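# Methods

## Scope and model

perimr implements one-sample Mendelian randomization from GWAS summary
statistics. The causal diagram is the standard instrumental-variable
triangle: genetic variants G proxy an exposure X (here a perinatal factor
such as birth weight), and the target is the causal effect θ of X on a
binary outcome Y (amblyopia), under the three IV assumptions — relevance
(G strongly associated with X), exclusion (G affects Y only through X) and
exchangeability (no confounding of G with Y). Relevance is enforced
empirically by the selection stage; exclusion violations are probed, not
guaranteed, by the pleiotropy diagnostics; exchangeability is a design
assumption.

All estimation is on summary data: per-SNP (β_X, σ_X) and (β_Y, σ_Y)
pairs. No individual-level genotypes are touched anywhere in the package.

## Pipeline stages and the parameters that matter

**Selection.** Genome-wide significance filter p < 1e-6 (strict
inequality; the published analysis deliberately used 1e-6 rather than
5e-8 to admit loci of unknown function), greedy LD clumping with r² ≥ 0.001
within 10,000 kb, and a user-supplied exclusion list for variants with
suspected direct outcome associations. Clumping ties on p-value are broken
by (chromosome, position, variant ID), making the output invariant to
input row order. The r² threshold is inclusive (≥), matching the published
exclusion wording; pairs absent from the LD table count as unlinked, so a
sparse LD extract suffices. Per-instrument strength is F = (β/σ)²; the
alternative (n−2)R²/(1−R²) form needs per-SNP R², which is not part of the
summary-statistics schema.

**Harmonization.** Outcome records are aligned to the exposure's effect
allele: allele swaps negate β_Y and complement the EAF; strand flips
relabel alleles through A↔T/C↔G; ambiguous cases resolve in a fixed order
(identical, swapped, complemented, complemented-and-swapped, palindromic
inference, mismatch). Palindromic SNPs are oriented by allele-frequency
concordance and dropped when either EAF lies inside the intermediate band.
The band default is [0.42, 0.58]: the source analysis says "intermediate
allele frequencies" without a number, and ±0.08 around 0.5 is the
community default (configurable). Palindromic SNPs *outside* the band are
retained via frequency inference rather than dropped wholesale — this
matches an alignment procedure that uses effect-allele frequencies for
palindromic SNPs; a strict mode drops all palindromic SNPs instead. A
missing EAF on a palindromic SNP forces a drop (conservative); on a
non-palindromic SNP it is tolerated.

**Estimation.** Wald ratio SEs use the first-order delta method
σ_Y/|β_X|; the second-order term is omitted, which keeps IVW exactly
equivalent to weighted regression through the origin. The random-effects
IVW is the multiplicative model with dispersion √(Q/(J−1)) deliberately
NOT floored at 1: the underdispersed case (Q/(J−1) < 1, random SE below
fixed SE) is a real pattern in small homogeneous instrument sets and is
the only convention consistent with published results showing a
random-effects SE about half the fixed-effects SE alongside a Q p-value
near 1. `floor_dispersion=True` restores the floored convention. The same
unfloored multiplicative residual scale applies to the MR-Egger
coefficient SEs (this is exactly the WLS residual variance, so the Egger
fit is delegated to statsmodels WLS). A side effect worth knowing: under
exact homogeneity the unfloored random-effects z-test is mildly
anticonservative (empirically ≈7% rejections at the 5% level in the test
suite's null calibration), while the fixed-effects z-test is calibrated —
that is the price of representing underdispersion faithfully.

Median estimators interpolate the ordered ratios against standardized
cumulative-weight midpoints s_j = (Σ_{k≤j} w'_k) − w'_j/2 and read off
s = 1/2; weights are scaled by their maximum before normalization so the
equal-weight case reduces bit-exactly to the simple median. The SE is a
parametric bootstrap (default 1000 replicates, seeded) redrawing each
θ_j ~ N(θ̂_j, se_j²) with weights held fixed; no analytic SE is published
for this estimator family, and the bootstrap is the conventional choice.

All pooled p-values are two-sided standard normal (not t); Q statistics
use χ² upper tails; the confidence level defaults to 95% (z = 1.959964).
Degenerate inputs: a single ratio is returned as its own "pooled" estimate
with a degenerate flag; medians and Egger require at least three
instruments; an exactly-fitting Egger regression (residual scale 0)
reports SE 0 with a point-mass CI rather than failing.

**Power.** The binary-outcome power uses the mRnd non-centrality
calculation: b01 = K(OR/(1+K(OR−1)) − 1), v = (K(1−K) − b01²)/(N·R²),
power = Φ(−z_{1−α/2} + |b01|/√v). With the published design values
(N = 417,030, K = 862/417,030, OR = 0.48, R² = 0.053, α = 0.05) this
evaluates to 0.9401 — the study's 94%. R² (variance in the exposure
explained by the instruments) is a direct input: it is not derivable from
the per-SNP schema and is taken from the run configuration (default
0.053). When invoked through the pipeline, the OR defaults to
exp(IVW random-effects β̂).

## The synthetic generator

The generator emulates the statistical structure of public biobank
summary statistics, not their content. For SNP j with MAF p_j ~
U(maf_range): b_j ~ N(0, τ²) for instruments (0 for null SNPs);
σ_Xj = (2p_j(1−p_j)N_X)^{−1/2} (standardized continuous trait);
β_Xj ~ N(b_j, σ_Xj²); for the binary outcome with case fraction K,
σ_Yj = (2p_j(1−p_j)N_Y K(1−K))^{−1/2} (logistic score-test approximation)
and β_Yj ~ N(θ·b_j + a_j, σ_Yj²), with direct effects a_j zero, N(0, sd²)
(balanced) or |N(0, sd²)| (directional). Even-indexed outcome records are
stored allele-swapped (β negated, EAF complemented) and a configurable
fraction of SNPs is palindromic, so harmonization is exercised on every
run; LD blocks are co-located SNP groups with a constant pairwise r².

Defaults are the study's conditions: 18 instruments, θ = −0.73, τ = 0.02,
exposure N = 262,966, outcome 862/416,168, no pleiotropy, independent
instruments (no LD blocks by default), MAF in (0.05, 0.5), 20% palindromic
SNPs, 100 null background SNPs. τ = 0.02 puts the instruments' F-statistics
in the tens-to-hundreds range typical of the anthropometric loci involved.

What the generator does not model — and therefore what passing tests do
not establish about real data: realistic LD from a haplotype model
(block r² is constant and block membership deterministic), one-sample
exposure/outcome overlap (exposure and outcome noise are independent, so
weak-instrument bias is toward the null rather than toward the
confounded observational estimate), population stratification, allele
frequency differences between the two GWAS, and p-value truncation or
column dialects of real releases (absorbed instead by `column_map` and
the warn-only p/z consistency check).

Monte-Carlo behaviour under the defaults, computed by the test suite: the
mean IVW estimate over 200 replicates at θ = −0.73 is attenuated toward 0
by ≈ τ²-to-noise regression dilution (observed bias ≈ +0.03, inside the
±0.05 recovery band), and the fixed-effects IVW z-test rejects a true
null ≈ 5–6% of the time at α = 0.05.

## Numerical and design choices

- Validation drops malformed rows (non-SNP alleles, non-positive SE,
  out-of-range EAF or p) with per-row logged reasons rather than failing
  the file; duplicated variant IDs and empty post-validation tables are
  hard errors.
- Positions are 1-based base pairs; the clumping window is interpreted as
  |Δpos| ≤ window_kb·1000 on the same chromosome.
- Stage randomness derives from one global seed through per-stage streams
  keyed by a CRC32 of the stage name, so rerunning the `mr` stage on the
  written harmonized table reproduces the report bit-for-bit and adding a
  stage never perturbs another stage's draws.
- report.json is serialized with sorted keys and full float precision;
  identical config + seed gives a byte-identical report.
- Test problem sizes: property and calibration tests use 18–200
  instruments and 30–1000 replicates, chosen to keep the full suite in a
  few seconds while leaving Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

- The Egger intercept test uses a normal reference distribution (a
  t-based variant is a documented possible refinement); with few
  instruments its calibration is approximate.
- The weighted-median bootstrap treats weights as fixed; uncertainty in
  σ_Y propagates only through the ratio redraws.
- No proxy-SNP substitution for instruments missing in the outcome GWAS,
  no MR-PRESSO/mode-based/multivariable estimators, no leave-one-out
  scans, and no LD computation from a reference panel — LD is a consumed
  input.
- Continuous-outcome power and sample-size inversion are not implemented.
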