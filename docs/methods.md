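# Methods

## The question and the estimands

The pipeline estimates whether a continuous moderator `M` (childhood
cognitive ability, modelled as standard normal) alters the association
between a T2D polygenic risk score `S` and two outcomes: glycated
hemoglobin (HbA1c, mmol/mol) and binary diabetes status. The estimands
are:

- the standardized main-effect β of `S` on HbA1c and the OR per SD of `S`
  on diagnosis;
- the standardized coefficient of the product term in
  `y ~ S + M + S×M`;
- the stratified "effect r": the Pearson correlation between `S` and the
  outcome within the below-median and above-median halves of `M`.

## Generative model (synthetic cohorts)

Genotypes are independent loci in Hardy–Weinberg equilibrium:
`d_ij ~ Binomial(2, f_j)` with `f_j ~ Uniform(0.05, 0.95)`. Linkage
disequilibrium is deliberately absent (a documented limitation, see
below). True per-SNP effects are `β_j ~ N(0, effect_sd²)` with an exact
`frac_null_snps` fraction set to zero (defaults 0.05 and 0.9). Reported
summary statistics add estimation noise with the GWAS-scale standard error
`se_j = 1/sqrt(2 f_j (1−f_j) N)`, `N = 150,000` by default (the scale of
large T2D meta-analyses); reported p-values are the two-sided normal tail
of `β̂_j/se_j`, so they are Uniform(0,1) under the null and p-value
thresholding enriches for truly non-null SNPs. A configurable fraction of
SNPs is reported with swapped alleles (20%), complementary-strand labels
(10%), or strand-ambiguous A/T–C/G pairs (10%) to exercise harmonization.

The true score `S` is the standardized `Σ_j β_j d_ij`. The moderator `M`
is standard normal, independent of genotype by default
(`moderator_score_corr` injects dependence for robustness checks). The
continuous outcome is

```
y = b_s·S + b_m·M + b_i·S·M + e,   e ~ N(0, noise_sd²)
```

affinely mapped to mean 38, SD 6 mmol/mol — a realistic HbA1c location and
spread for a non-diabetic-dominated older cohort; the label is cosmetic
because every analysis is scale-invariant. With `noise_sd = None` (the
default) the noise variance completes Var(y) to 1, making `b_s`, `b_m`,
`b_i` standardized-scale estimands. The binary outcome thresholds a second
liability with the same linear predictor and fresh noise at its empirical
0.912 quantile, so the realized prevalence is 8.8% (83/940 at the default
sample size) — an explicit design choice over a theoretical-quantile
threshold, trading a little prevalence randomness for exact calibration at
any beta configuration.

Defaults `b_s = 0.16`, `b_m = −0.13`, `b_i = −0.08` put the score and
moderator main effects at the magnitudes such a cohort exhibits and imply
stratum correlations of about 0.22 below and 0.10 above the moderator
median. For exact stratum targets, `calibrate_stratified_effects(r_low,
r_high, b_m)` inverts the closed form

```
r_g = (b_s + b_i m_g) / sqrt(1 − b_m²(2/π) + 2 b_s b_i m_g),   m_g = ∓√(2/π)
```

which follows from S ⟂ M, unit total variance, and the half-normal moments
of M within a median stratum.

All randomness flows from one integer seed through four named substreams
(allele frequencies, genotypes, summary statistics, phenotypes) derived
via `numpy.random.SeedSequence`, so stages are independently reproducible
and identical configs give bit-identical cohorts. Each sample also gets
age (N(69.55, 0.85²)), sex (Bernoulli 0.5), BMI (N(27.5, 4.4²)) — all
independent of the outcome model, serving as null covariates — and an
`insulin_therapy` flag set for ~13% of cases (≈11 of 83), emulating the
possible-Type-1 subgroup used by the exclusion sensitivity analysis.

### What the generator does not emulate

No LD between loci, no assortment or population structure, no
genotype-moderator correlation by default, no HbA1c right-skew, no
measurement error in the moderator, and covariates carry no true effects.
Passing tests therefore demonstrate the *procedures* are correct and
calibrated under a well-specified model; they do not certify behavior
under confounding, stratification or model misspecification in real
cohorts.

## PRS engine

Harmonization resolves each summary-statistics SNP against the genotype
matrix in a fixed order: direct allele match; allele swap (dosage recoded
`d → 2−d`); strand complement, then match or swap. A/T and C/G pairs are
excluded under the default policy because allele labels cannot identify
the strand (frequency-based rescue is out of scope). Remaining SNPs —
absent or allele-incompatible — are dropped and counted. The per-SNP
disposition table and the five-way count summary are written with every
run; standardized scores are invariant to allele-label orientation (tested
to 1e-10).

Scoring is `score_i = Σ_j w_j d_ij`, accumulated SNP-by-SNP so the
vectorized code is bit-identical to a per-sample loop-and-sum. Missing
dosages: `mean_impute` (default, matching common scoring-tool semantics)
substitutes the SNP's sample mean dosage; `omit_and_rescale` drops the
term and rescales by total/observed SNP count. With no missingness both
policies coincide exactly.

The threshold grid {1, 0.5, 0.1, 0.05, 0.01, 1e-3, 1e-4, 5e-8} yields one
primary plus seven stricter score variants; thresholds must be strictly
descending, SNP sets nest, and a column retaining no SNPs (or with zero
variance) is flagged degenerate rather than zero-filled. Standardization
uses the sample SD with n−1 — stated explicitly because every "per SD"
estimate depends on it. No LD clumping is performed; the thresholding
entry point accepts a pre-filtered SNP set should one be needed.

## Regression models

Linear fits are OLS on listwise-complete cases with the outcome and all
continuous predictors z-scored first; the interaction column is the
product of the z-scored components and is *not* re-standardized, keeping
the main effects interpretable at the moderator mean. Wald 95% CIs and
two-sided p-values use the t reference. Logistic fits use IRLS
(statsmodels GLM/Binomial, convergence tolerance 1e-10, ≤100 iterations);
ORs per SD are `exp(coef)` with Wald CIs exponentiated from the log-odds
scale. Complete or quasi-complete separation (the IRLS separation
diagnostic, non-convergence, or |log-OR| > 15 per SD) raises an explicit
error instead of returning an absurd OR. Fewer than 10 complete cases or
10 events, single-class outcomes, constant predictors and rank-deficient
designs are all rejected with named errors. p-values are clamped into
(0, 1] so that a numerically-zero tail probability reports the smallest
positive float rather than 0.

The default models carry no covariates; age/sex/BMI adjustment is opt-in
per call or via the run config. Wald interaction tests are the default
(an LRT could be added, but the Wald p is what the cross-threshold summary
tabulates). With only ~83 events at n = 940 the logistic interaction test
is underpowered relative to the linear one — the type-I calibration test
covers the linear family, and low-event-count anticonservativeness of the
logistic Wald test is a known caveat.

Median split: samples with `M ≤ median` form the low stratum (ties-low is
deterministic; `tie_rule="high"` is available since the tie convention is
genuinely arbitrary). Within a stratum, the continuous-outcome effect r is
the standardized simple-regression β, identical to the Pearson
correlation; for the binary outcome the stratum model is logistic and
effect r is the point-biserial correlation. Strata under 10 complete cases
are errors. No multiple-testing correction is applied across the eight
threshold scores — they are reported as a robustness family, not an
inference family.

Sensitivity refits re-estimate the chosen model after dropping
flag-positive samples and/or adding one covariate, returning both fits and
the change in the score and interaction coefficients.

## Numerical and design choices

- HbA1c diagnostic cutoff 48 mmol/mol (6.5%), inclusive ≥, configurable.
- Missing tokens in dosage TSVs: `NA`, `.`, empty; phenotype CSVs use
  pandas NA semantics; models use listwise deletion and report `n_used`.
- Degenerate inputs fail loudly: zero-variance scores, empty harmonization
  overlap, empty threshold columns, all-missing SNPs under imputation.
- Summary-statistics writers use `%.17g` so text round-trips are exact.
- The pipeline manifest contains input hashes, seed, config echo and
  version — and no timestamps — so reruns are byte-identical.
- Monte-Carlo test sizes: the calibration suite uses 64-SNP cohorts (the
  outcome model depends on the score only through its standardized
  aggregate, so SNP count affects only CLT quality), n = 940 for type-I
  error and stratified recovery, and n = 10,000 × 500 replicates for
  interaction recovery and CI coverage.

## Known limitations

Independent loci only; p-value thresholding without LD clumping; no
reference-panel imputation; no X-chromosome dosage conventions; no formal
mediation analysis for BMI (covariate adjustment only); single-moderator,
single-interaction models. The alternative-to-median splitting of the
moderator (e.g. tertiles) is intentionally left as a configuration hook
rather than guessed at.
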