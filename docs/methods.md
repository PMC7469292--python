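# Methods

## The two designs and their estimands

**Serological arm.** The observational design is a 1:1
incidence-density-matched case-control study nested in a prospective
cohort: each incident colorectal cancer case is matched to one cancer-free
control on sex, age at blood collection, center, fasting status (and, in
women, menopausal status and hormone-therapy use). The exposure is
pre-diagnostic unconjugated bilirubin (UCB, μmol/L), analyzed as
log-transformed values standardized per 1-SD. The estimand is the
conditional odds ratio per 1-SD of log-UCB from conditional logistic
regression, which conditions out all matched-set-level confounding.

**MR arm.** The causal design is a two-sample Mendelian randomization:
per-variant associations with total bilirubin (SD units, from a large
biobank GWAS) are combined with per-variant associations with colorectal
cancer (log OR, from case-control consortia that exclude the biobank, so
the two samples do not overlap). The estimand is the causal log OR per
1-SD of bilirubin. The instrument is unusual in that a single *UGT1A1*
promoter-tagging variant explains 16.9% of exposure variance while the
remaining 114 variants together explain 3.1%; the analysis therefore
treats the lead variant (single-variant Wald ratio) separately from the
remaining instrument (full estimator suite).

## Synthetic-data generator

Real cohort and consortium data are access-controlled, so the generator
reproduces the statistical structure the analysis assumes. What it
emulates:

- **Exposure**: log-normal UCB. Defaults match the measured control
  distributions — men mean 4.0, SD 2.2 μmol/L (meanlog 1.254,
  sdlog 0.514); women 3.4, SD 1.9 (1.088, 0.521).
- **Lead genotype**: Hardy-Weinberg at MAF 0.35 (the observed
  bilirubin-increasing C-allele frequency), shifting standardized
  log-exposure by 0.609 SD per allele so that 2·MAF(1−MAF)·β² = 0.169.
  The residual SD is shrunk so standardized log-exposure has unit
  variance in truth.
- **Case assignment**: within each pair the case is drawn with the exact
  conditional probability exp(lp₁)/(exp(lp₁)+exp(lp₂)) given both
  members' linear predictors. This Rasch-type construction makes the
  planted coefficient *exactly* the conditional-logistic estimand, so
  recovery tests are unbiased by construction. An optional quadratic term
  in standardized log-exposure supports nonlinearity power studies.
- **Covariates**: continuous (BMI, height) as normals and dietary intakes
  as log-normals with sex-specific moments from the control
  distributions; categorical covariates (education, smoking, physical
  activity, and in women hormone-therapy use and menopausal status) with
  the control frequencies, and a configurable missingness rate (default
  2%) that produces an explicit "missing" level. Matching factors (age,
  center, fasting status) are pair-constant. Sub-site labels follow the
  observed case frequencies per sex; a liver amino-acid panel (BCAA,
  tyrosine, phenylalanine) uses normal-range plasma values.
- **Summary statistics**: true per-variant exposure effects are scaled so
  realized variance explained is exactly 0.169 for the lead variant and
  0.031 over the rest. Observed effects add independent noise with the
  conventional first-order SEs, 1/√(2pq·n) for a standardized trait and
  1/√(2pq·n_cases·n_controls/N) for a log OR; MAFs are uniform on
  [0.05, 0.5]. Optional zero- or nonzero-mean pleiotropy and planted
  outlier offsets act directly on the outcome effects. Exposure and
  outcome noise are independent (two-sample, non-overlapping).

What it does **not** emulate: linkage disequilibrium between instrument
variants (the design prunes to independence), genotype imputation
quality, population stratification, laboratory batch effects, or
selection/ascertainment artifacts. Passing recovery tests therefore shows
that the estimators are correct for the assumed sampling model, not that
the real-data estimates are free of those biases.

Default standardization of log-exposure is sex-specific (all models are
sex-stratified); pooled moments are available by flag.

## Numerical and inferential choices

- **Conditional logistic fits** use the exact pair-difference reduction
  (a no-intercept binomial likelihood on case-minus-control covariate
  differences), maximized by Newton iterations with step-halving,
  convergence when the step falls below 1e-9 and the log-likelihood
  changes by less than 1e-10. Pairs with all-zero differences contribute
  no information and are dropped from `n_pairs_used`. A coefficient
  exceeding 15 in absolute value triggers a separation error naming the
  covariate; in stratified fits (interaction and sub-site analyses) a
  separated *dummy* column is instead collapsed into the reference level
  with a warning, which is what keeps sparse strata estimable — the
  exposure term itself is never silently dropped. A generic stratified
  conditional likelihood is retained through the competing-risks sub-site
  model, which for 1:1 sets factorizes into independent per-site fits
  with the exposure coefficient indexed by the case's sub-site
  (overlapping colon lesions count toward all-colon only).
- **Spline dose-response** uses a three-knot restricted cubic spline at
  the 10th/50th/90th percentiles (one nonlinear term, zero at and below
  the first knot, linear beyond the last, scaled by (k₃−k₁)²), fitted on
  the raw exposure scale by default with the plotted curve referenced to
  the first knot; a log-scale option exists and is the scale on which the
  generator's planted effect is exactly linear, hence the scale used for
  type-I-error calibration.
- **Wald-ratio SE** is first-order (σᵧ/|β̂ₓ|) by default; the
  second-order form is available by flag.
- **Likelihood-based MR** profiles the per-variant means out analytically,
  leaving −½Σ(β̂ᵧⱼ−θβ̂ₓⱼ)²/(σᵧⱼ²+θ²σₓⱼ²), maximized by Brent's method
  started at the fixed-effect IVW estimate; the SE comes from the
  numerical curvature at the maximum. Cross-correlation is fixed at 0
  because the two samples do not overlap.
- **MR-Egger** inference is plain weighted-least-squares theory: residual
  variance estimated with k−2 df and t-based p-values for slope and
  intercept, with instruments oriented to non-negative exposure effects
  before fitting. The estimator is exactly equivalent to a generic WLS
  solver (tested to 1e-10).
- **Weighted median** interpolates the weighted CDF of the Wald ratios at
  cumulative weight 0.5 (ties resolved by linear interpolation =
  midpoint); **mode-based** estimation is the argmax of a normal-kernel
  density over the ratios on a 2048-point grid with bandwidth =
  bandwidth_factor × 0.9·min(SD, 1.4826·MAD)·k^(−1/5) (modified Silverman
  rule; factor defaults to 1, simple unweighted mode). Both use
  parametric bootstrap SEs (default 1000 resamples) with explicit seeds;
  no global RNG state anywhere.
- **MR-PRESSO** computes the observed statistic as inverse-variance-
  weighted leave-one-out residual sums of squares. Null replicates redraw
  both effect vectors from their SEs around a *single homogeneous slope*
  — the median of the leave-one-out IVW estimates. The description this
  test descends from uses each variant's own leave-one-out slope as its
  simulated mean; with this study's extremely asymmetric instrument that
  injects the spread of those slopes into the null and makes the global
  p-value severely conservative, whereas the homogeneous-slope null is
  uniform under no pleiotropy and loses no outlier power. Empirical
  p-values use (r+1)/(n+1) and are never exactly zero; the outlier test
  is Bonferroni-adjusted at α = 0.05 by default; the distortion test
  compares the estimate shift against random same-size removals of
  non-outlier variants and is reported as not applicable when nothing is
  flagged. Defaults: 1000 simulations, minimum 4 instruments.
- **Heterogeneity**: fixed-effect Cochran Q; I² truncated at 0; the
  normal 95% quantile is fixed at 1.959964 throughout for bit-for-bit
  reproducibility. Standard errors can be reconstructed from printed
  OR (95% CI) triples via (ln hi − ln lo)/(2·1.959964).
- **Power** for a binary-outcome MR uses the normal approximation
  Φ(√(N·R²·φ(1−φ))·|ln OR| − z₀.₉₇₅) with φ the case fraction. At the
  sex-stratum sample sizes and R² = 0.20 this gives ≈ 0.87 at OR 1.065;
  the approximation is documented rather than matched to any published
  power claim.
- **Harmonization** aligns outcome to exposure alleles (flipping signs
  and frequencies when recorded on the opposite allele), drops A/T and
  C/G variants by default or substitutes a supplied proxy only when its
  LD R² exceeds 0.8, never infers strand from allele frequency, and
  orients the final set to the exposure-increasing allele (all MR
  estimators are invariant to this orientation; plots then share a
  positive x-axis). QC removal reasons are reported in filter order:
  call rate (default minimum 0.98, the stricter consortium threshold),
  Hardy-Weinberg p (1e-4), then MAF (0.01).
- **Liver filters**: BTR = BCAA/tyrosine and Fischer's ratio =
  BCAA/(tyrosine+phenylalanine); default exclusion thresholds 4.4 and
  1.8 are conventional clinical screening cut-offs and are configurable.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen to keep the suite fast while leaving
the statistical conclusions unambiguous: conditional-logistic recovery
runs 500 replicates at the study's own 658/728 pairs; Wald-ratio recovery
uses the study's full GWAS sample sizes; type-I-error calibrations use
1000 replicates (25-variant instruments for the Egger intercept,
300-pair cohorts for the spline test); PRESSO calibration uses 500
null replicates of 10-variant instruments at 300 simulations each.
Acceptance-script replicate counts are recorded in its JSON output.

## Limitations

- The 1:1 pair-difference reduction is exact only for 1:1 matching; m:n
  sets are out of scope.
- No multivariable MR, correlated-instrument IVW, or Bayesian estimators;
  no multiple imputation of missing covariates (missingness is modeled as
  its own category, as in the original analysis).
- The profile-likelihood SE is a curvature approximation; for very weak
  instruments a full likelihood-ratio interval would be preferable.
- Bootstrap SEs for the median/mode estimators assume normal sampling of
  the per-variant effects.
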