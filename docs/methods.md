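# Methods

## The model

All inference rests on the single-random-effect mixed linear model

    y = Xb + u + e,    u ~ N(0, A σ²ₒ),    e ~ N(0, I σ²ₑ),

with y a growth trait over n individuals (body weight at 84 days, or the
average daily gain of one of the three periods ending at 84 days), X the
fixed-effect design (intercept, a sex dummy, two birth-season dummies —
reference coding, rank-checked), and A the expression-level relationship
matrix (ORM)

    A_jk = (1/m) Σᵢ (x_ij − μᵢ)(x_ik − μᵢ)/σ²ᵢ  =  (ZᵀZ/m)_jk ,

where Z holds m standardized expression rows.  The target quantity is
ρ² = σ²ₒ/(σ²ₒ+σ²ₑ), the proportion of phenotypic variance attributable to
genome-wide expression.

The published form of the ORM element separates the two centred factors
with a division sign; the product form above is the only reading
consistent with a covariance interpretation (and with the definition used
by the mixed-model software family this matrix comes from), and is what
this package implements.

## Expression processing

* **Expressed filter** (before normalization): keep a feature iff its raw
  count is ≥ 2 in *strictly more than* 30% of individuals.  The strict
  inequality matters at the boundary: 3 of 10 individuals is dropped, 4 of
  10 kept.  Filtering on raw counts before TMM also stabilizes the
  trimmed-mean factors.
* **TMM** with the canonical trims (30% on M-values, 5% on A-values),
  precision weights from the binomial delta-method variance, reference
  column chosen by upper-quartile/library-size ratio closest to the mean,
  factors rescaled to geometric mean 1.  The implementation is checked
  against an independent reference implementation's factors frozen into
  the test suite; note the factors are invariant to scaling a column's
  counts only up to an O(1/N) effect of the count-level weights (the
  reference implementation behaves identically).
* **CPM**: countᵢⱼ / (Nⱼ fⱼ) × 10⁶ with Nⱼ the library size and fⱼ the TMM
  factor.  A log2(CPM+1) variant exists behind `log_cpm` for users who
  prefer variance-stabilized input; the default is plain CPM.
* **Standardization** uses the population (1/n) variance, so the ORM's
  diagonal averages to exactly 1 and trace(A) = n.  This makes ρ² read
  directly as a variance fraction; the sample-variance alternative only
  rescales σ²ₒ by (n−1)/n.  Zero-variance features are dropped with a
  warning.

## REML

With one relationship matrix plus an identity residual, the covariance is
diagonal on A's eigenbasis: V = diag(σ²ₒ λ_k + σ²ₑ).  `fit_reml` rotates y
and X once (one O(n³) eigendecomposition, cached on the
`RelationshipMatrix` and shared with the association scans), profiles out
the fixed effects and the residual variance analytically, and optimizes
only the ratio γ = σ²ₒ/σ²ₑ: a 33-point sweep of log₁₀γ over [−8, 8] plus
the γ = 0 boundary, followed by bounded Brent refinement around the best
grid point.  Each likelihood evaluation is O(n).  The sweep-then-refine
scheme cannot diverge and finds the global profile optimum to optimizer
tolerance (~1e-10 on log₁₀γ); invariances that are exact mathematically
(shift of y, rescaling of y) therefore hold to ~1e-4 on ρ², not to machine
precision.

Standard errors come from the inverse expected (Fisher) information of
(σ²ₒ, σ²ₑ) at the optimum — identical to the average-information matrix at
convergence for this model class — reduced to O(np²) sums by the diagonal
structure.  se(ρ²) follows by the delta method.  Degenerate outcomes are
first-class results, not exceptions: a boundary solution (σ²ₒ = 0) is a
converged fit with a flag; an information matrix that is not positive
definite, or an ORM proportional to the identity (only σ²ₒ+σ²ₑ is then
identifiable), yields `converged=False`, which the report prints as
"Not converged".

`fit_reml_multi` provides dense average-information REML with step
halving and a non-negativity floor for the multi-component covariances
that arise when association features are stratified into bins; it is
O(n³) per iteration and intended for single-study sample sizes.

## Association testing

The preliminary scan (`moa_scan`) holds variance parameters at the null
REML fit, whitens once on the ORM eigenbasis, and computes each feature's
generalized-least-squares effect and 1-df Wald chi-square in O(n).

`moment_test` removes the double-fitting problem: the tested feature is
excluded from the random-effect side.  Features are stratified by
preliminary p-value (default two bins split at the Bonferroni line; an
empty top bin collapses to one component), per-bin ORMs are built, and
variance components are fitted once per bin configuration — exact, not an
approximation of convenience: the average over targets of the
leave-one-out ORM (mA − zᵢzᵢᵀ)/(m−1) is algebraically the full ORM, so
the full-ORM fit *is* the per-pattern fit.  Per target, the covariance is
a rank-one downdate of the shared per-bin matrix; the inverse square root
of I − c z zᵀ is itself a rank-one update, so the per-feature GLS reduces
to OLS on transformed vectors finished by a QR residualization (chosen
over normal equations, which lose ~6 digits to cancellation here).  Cost:
one eigendecomposition per bin, O(n·p) per feature after that.

Calibration has two regimes, both asserted in the tests. Under the strict
null (expression unrelated to the trait) the leave-target-out test is
calibrated: type-I error 0.05 and λ ≈ 1.  Under an infinitesimal
polygenic background with no individually causal feature, the excluded
target's *own* random-effect share becomes testable signal, so
E[χ²] ≈ 1 + nσ²ₒ/(mσ²ₑ) by construction (measured λ ≈ 1.18 at n = 500,
m = 1,000, ρ² = 0.3, matching that formula).  This is the intended
behaviour of leave-target-out testing, not inflation from stratification;
the single-ORM scan, which shrinks the target through the random effect,
stays at λ ≈ 1 in both regimes.

Diagnostics: λ = median(χ²)/0.4549364 (the 1-df chi-square median), with
a seeded percentile-bootstrap 95% CI over features — the CI construction
used for the published intervals is not derivable from their text, so no
attempt is made to match their widths.  Significance: threshold
0.05/n_tests over *all* tested features; when nothing passes, the
suggestive list holds the top 20 protein-coding features by p-value
(ties, though almost surely absent, break lexicographically for
deterministic reports).  Non-coding features count toward n_tests but
never enter the suggestive list.

## Phenotype QC

Per weigh age, values outside median ± k·c·MAD are outliers (k = 3;
c = 1.4826, the Gaussian-consistency constant, configurable to 1.0 for
the literal raw-MAD rule — the underlying QC literature recommends the
consistent form).  An individual failing at any age is excluded entirely.
A zero MAD collapses the band to the median and warns.  ADG for the
periods 35→84, 56→84 and 70→84 days uses the fixed period lengths
49/28/14 days (overridable).  The descriptive report's ratio column is
mean/SD: that is the quantity the reference summary table prints under
its "CV" heading (its BW84 row: 1981.61/289.84 = 6.84), and the report
labels it accordingly.

## Synthetic data

The generator emulates a ~115-rabbit growth study with long-read bulk
muscle expression:

* **Counts**: gene abundances log-normal (σ = 1.5), library sizes
  log-normal around 6.6 M reads (CV 0.15 by default), counts
  Gamma-Poisson with common dispersion 0.1.  Expression breadth is
  enforced by zero-inflation masks: a configurable fraction of genes
  (default 45%) has count ≥ 2 in more than 90% of individuals, another
  fraction (default 21%) in fewer than 10%, the remainder in between —
  class membership is exact by construction, which the breadth tests
  exploit.  Annotation assigns 21 autosomes, coordinates, an 80/20
  protein-coding/lncRNA biotype mix and a 35% novel-gene rate.
* **Phenotypes**: the 84-day weight is mean + sex + season + Zᵀs +
  optional per-feature fixed effects + residual, with s ~ N(0, σ²ₒ/m)
  drawn per gene and Z the standardized matrix produced by the package's
  *own* filter/TMM/CPM/standardize pipeline.  Because Var(Zᵀs) = Aσ²ₒ for
  the very ORM used in fitting, the REML model is exactly correctly
  specified and recovery of ρ² is unbiased — the closed loop the
  acceptance analysis relies on.  σ²ₑ is set so σ²ₒ/(σ²ₒ+σ²ₑ) equals the
  requested fraction on the scale of the 84-day-weight variance
  (SD 289.84 g).  Earlier ages follow the monotone mean growth trend
  (means backed out of the period daily gains; SDs shrunk proportionally
  to the mean) with a shared latent size factor (weight 0.7) inducing
  realistic cross-age correlations.  Default fixed effects: +80 g for
  males, (0, +40, −40) g across the three birth seasons — a few percent
  of a within-group SD, the magnitude expected of husbandry covariates.
* **Outliers**: a stated fraction of individuals receive one body-weight
  record displaced by ≥ 10 SD (direction random, positivity preserved),
  guaranteeing detection by any 3×MAD convention.

What the generator does **not** emulate: isoform structure, eQTL
genotypes, batch/lane effects, count-level correlation between genes
beyond what library-size scaling induces, and non-Gaussian trait
residuals.  Passing recovery tests therefore demonstrate correctness of
the estimator under its own assumptions, not robustness to the full
messiness of real transcriptome data.

## Problem sizes and numerical choices

The recovery analysis uses n = 1,000 individuals × m = 500 features ×
100 replicates per target — large enough that the Monte-Carlo error of a
mean estimate (~0.005) is well inside the ±0.03 acceptance band, small
enough to run in minutes.  Test simulations use n = 500, m = 1,000 for
calibration (where m drives the precision of type-I/λ estimates) and
n ∈ [6, 500] elsewhere.  Eigenvalues are clipped at 0 before use (the ORM
is PSD up to round-off); symmetry is enforced as (A+Aᵀ)/2 after the BLAS
product; REML convergence tolerance is 1e-8 on the restricted
log-likelihood; the eigendecomposition is computed once per relationship
matrix and reused by REML and both scans.

## Known limitations

* Variance components in the association scans are held at their
  bin-pattern estimates rather than re-fitted per target — the standard
  efficiency approximation; exact per-target REML would cost one O(n³)
  fit per feature.
* Exclusion of features *correlated* with the target (beyond the target
  itself) is off by default; only the target leaves the random effect.
* The bootstrap λ CI resamples features independently, ignoring
  inter-feature correlation; its coverage is exact only as correlation
  vanishes.
* `fit_reml_multi` is dense and not suited to n much beyond a few
  thousand.
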