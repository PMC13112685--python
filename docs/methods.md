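# Methods

This note documents the statistical models behind `bmiburden`, the
assumptions they make, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices that affect results.

## 1. Data model

Everything is stratified by (year, county, age group, sex,
race/ethnicity) — a *stratum*.  Uncertainty is carried as a `DrawMatrix`
(strata × draws); every aggregation, age-standardization, product, and
ratio is computed draw by draw, and point estimates (means) and 95%
uncertainty intervals (2.5th/97.5th percentiles, linear interpolation
between order statistics) are taken only at the end.  The final draw count
is `n_sets × n_draws` (defaults 10 × 100 = 1000): one block of model draws
per crosswalk-adjusted dataset, so that self-report-correction uncertainty
and model uncertainty both propagate.

## 2. Self-report crosswalk

**Model.**  Within each sex, the gap *g* = measured − self-reported BMI is
regressed by OLS on (i) a piecewise-linear (tent) basis in the record's
within-sex quantile of self-reported BMI, with one coefficient per grid
quantile (deciles 0.1…0.9 by default), and (ii) age-group and race
indicator offsets.  Two extra "tail-guard" knots are placed on each side
between the outer grid quantiles and 0/1; their coefficients absorb the
steep open tails and are discarded, so the outermost grid coefficients
estimate the gap *at* their quantiles rather than a tail average (with a
nearest-bin design the 0.9-decile coefficient is a tail mean, biased by
several tenths of a BMI unit).

**Application.**  A record's correction is the linear interpolation of the
quantile coefficients across the sex-specific BMI knots (the self-report
quantiles of the calibration data), constant beyond the outermost knots;
adjusted BMI is clipped to (10, 80) kg/m².  If the fitted corrections
would make x ↦ x + Δ(x) decreasing anywhere (quantile crossing), the
corrected knot values are isotonically projected and the repair is logged.

**Uncertainty.**  Each of the `n_sets` adjusted datasets comes from an
independent nonparametric bootstrap refit.  The bootstrap is stratified by
(sex, age, race) cell so a resample can never lose a cell (an empty cell
is a fitting error by contract).

**Assumptions and limits.**  The correction is additive and separable in
(quantile, age, race); bias is assumed not to vary by place, matching the
design of national calibration data.  With noisy self-reports the
quantile-conditional expectation E[g | rank of s] is not exactly the
inverse distortion (an errors-in-variables effect): with reporting noise
of 1 BMI unit the endpoint corrections deviate from the analytic inverse
of the generator's distortion by roughly 0.2–0.4 units, while with
noise-free calibration they agree to ~0.02.  The correction nevertheless
removes most of the bias — that is the property the tests assert.

## 3. Prevalence models (small-area estimation)

Per (sex, race) and outcome *o* ∈ {P(BMI ≥ 25), P(BMI ≥ 30 | BMI ≥ 25)},
with cells indexed by (year *t*, county *c*, age group *a*):

- Likelihood: binomial on the design-weighted proportion with the
  design-effect effective sample size (Σw)²/Σw² (for the conditional
  outcome, the ESS of the records with BMI ≥ 25).  Weighted proportions
  with ESS are the standard way to feed weighted survey data to a
  binomial small-area model.
- Linear predictor: logit p = β₀ + β·z(c) + u_c + α_a + τ_t with
  z(c) the three standardized county covariates (poverty rate and share
  foreign-born, both race-specific; log population density), u an
  intrinsic pairwise-difference (ICAR) spatial effect on the county
  adjacency graph, α i.i.d. normal, τ a first-order random walk over
  consecutive years.  The improper ICAR/RW1 priors are identified by a
  soft sum-to-zero constraint (precision on the block mean equivalent to
  sd 0.01) alongside a weak N(0, 10²) prior on the fixed effects.
- Inference: empirical-Bayes Laplace approximation.  For fixed variance
  parameters θ = log sd of each random-effect block, the latent field is
  maximized by damped Newton iterations (the binomial-logit posterior is
  concave); θ maximizes the Laplace-approximate marginal posterior with
  half-normal(1) priors on the sds (Nelder–Mead); draws come from
  N(ẑ, H⁻¹) at the optimum.  This is the same approximation family used
  by TMB-style latent Gaussian small-area models; plug-in θ̂ slightly
  understates hyperparameter uncertainty, which the calibration tests
  bound (stratum-level 95% intervals cover truth for ≥ 85% of strata on
  replicated synthetic worlds; observed ≈ 92%).
- Cells with no respondents contribute no likelihood and are predicted
  entirely by the smoothing structure; non-convergence raises an error
  carrying the diagnostics, never a silent result.

Poststratification attaches stratum population counts to the modelled
cells; aggregates over any axis (county, sex, race, nation) are
population-weighted means per draw.  Obesity prevalence is the draw-wise
product of the two outcome models' draws; combining the models this way
keeps obesity ≤ P(BMI ≥ 25) by construction.

**On survey weights and non-response.**  The generator's survey weights
are the inverse of the *design* inclusion probability (equal expected
sample per county, proportional to population within county).  The
stratum-level response propensity is deliberately *not* in the weights —
it is unknown to the analyst, which is exactly the non-response bias the
model-plus-poststratification step corrects (tested: the poststratified
national estimate beats the raw weighted estimate in ≥ 90% of replicates).
This mirrors real surveys, where design weights are known but differential
response is not.

## 4. Exposure distributions

A two-parameter log-normal truncated to (10, 80) kg/m² is fit per stratum
and draw by solving {P(X ≥ 25) = p₂₅, P(X ≥ 30) = p₃₀} on the truncated
distribution (root-finding from the closed-form untruncated solution,
refined by a fixed-point pass that accounts for truncated mass; residual
tolerance 1e-9, verified to ~1e-15 on a grid of targets).  Two constraints
exactly identify two parameters, so the family is exactly as expressive as
the information available; the `family` argument leaves room for mixture
ensembles without interface changes.

Truncation shrinks the feasible set of tail pairs: the boundary is the
σ → ∞ limit of the family (densities ∝ exp(λ·log x) on the support),
computable by one-dimensional root-finding (`feasible_p30_max`).  Targets
beyond the boundary raise a convergence error with diagnostics by
default; the pipeline's distribution-fit stage opts into projecting such
(rare, extreme-draw) targets just inside the boundary while keeping p₂₅,
which stays visible as achieved_p30 ≠ target in `exposure_params.csv`.

## 5. Attribution

Relative-risk curves are continuous in BMI, stored on a 0.1 kg/m² grid
with monotone piecewise-cubic interpolation, and normalized to RR = 1 at
and below the TMREL's upper bound (21 kg/m²).  Using the interval's upper
bound as the normalization point is the conservative reading of an
interval TMREL with unspecified internal weighting.  Synthetic curves are
log-linear or J-shaped (quadratic on the log scale) in (BMI − 21)₊ with
non-negative coefficients, which guarantees the invariants by
construction.

PAF = 1 − 1/E[RR(X)], with E[RR(X)] by adaptive quadrature (absolute
tolerance 1e-10); the mass at and below the TMREL, where RR ≡ 1,
contributes analytically and only the risk-bearing tail is integrated.
Quadrature agrees with a 10⁶-point trapezoid to ~1e-7.  Attributable
YLL rate = PAF × total cause-specific YLL rate and attributable count =
rate × population / 100,000, per draw; no mediation or risk-overlap
adjustment is applied (single-risk attribution; the curves consumed as
input are assumed to encode any such upstream adjustment).  A point-mass
exposure class provides the closed-form oracle PAF = (r − 1)/r.

## 6. Summaries

- Significance of a pairwise difference: share of paired difference draws
  strictly greater than zero below 0.025 or above 0.975 (draws exactly
  zero count as not-greater); requires ≥ 40 draws so the 2.5% tail is
  resolvable.  Differences use paired draw indices, preserving the
  correlation induced by shared crosswalk sets.
- Coefficient of variation: population (divide-by-n) standard deviation
  over the mean — the natural convention for dispersion over an
  exhaustive set of counties; computed on point estimates.
- Age standardization uses reference weights (e.g. a census adult age
  structure), never the stratum's own populations; the pipeline derives
  its reference from the synthetic world's first-year population.
- Masking: any (county, race) with mean annual population strictly below
  1000 (the default threshold) is masked in every output; masked rows
  carry no values.
- Aggregation and standardization are always performed on draws before
  summarization.  Reversing the order leaves means unchanged but distorts
  intervals; a test pins this.

## 7. The synthetic world

The generator emulates, at miniature scale, the structure of the real
estimation problem: a connected 2-D lattice county graph with optional
extra edges (the minimal faithful analogue of a county contiguity graph);
county × race covariates; true stratum BMI distributions whose tail
prevalences follow logistic models in covariates, age, sex, race, year
trend, and a spatially smooth county effect (coefficients recorded for
recovery tests); hinge self-report distortion b(x) = x − (δ₀ + δ₁(x−25)₊)
with cell-specific deltas (defaults δ₀ = 0.4 plus 0.25 for women and 0.15
for the oldest group, δ₁ = 0.08 — the documented direction and rough
magnitude of self-report error); multinomial survey counts with a
stratum response propensity declining in true obesity
(strength 0.5 on the standardized scale); calibration pairs with
mean-zero reporting noise (sd 1.0 kg/m²); cause-specific total YLL rates
with age gradients; and default race intercepts sized so the default
world reproduces the observed ordering and rough magnitudes of US adult
obesity by race/ethnicity (≈ 49/48/45/39/21% for Black/AIAN/Latino/White/
Asian populations).

It does **not** emulate: real geography or unstable county boundaries,
coarsened geographic reporting, racial/ethnic misclassification, the
pooling of small populations into "Other" categories in calibration data,
age-varying relative risks, or any COVID-era dynamics.  Passing tests
therefore demonstrate that the estimation chain recovers truth *when its
assumptions hold and the data-generating process is of the assumed form*;
they do not certify performance on real survey data.

Worlds are pure functions of (config, seed); surveys and calibration of
(world, seed).  Problem sizes used by the test suite and the acceptance
script — 4–9 counties, 2–3 years, 2 age groups, 2–3 races, surveys of
2000–4000 respondents per year, 2 crosswalk sets × 25–50 draws — are the
package's desk-scale defaults for validation runs; all constants of the
full-scale analysis (10 sets × 100 draws, thresholds 25/30, TMREL 20–21,
mask 1000) remain the configuration defaults.

## 8. Known limitations

- Plug-in Laplace inference ignores hyperparameter uncertainty; intervals
  are slightly anti-conservative in very sparse worlds.
- The additive quantile crosswalk has an inherent errors-in-variables
  bias at the distribution tails when reporting noise is large.
- The exposure family is a single two-parameter distribution, not an
  ensemble; strata whose true BMI distribution is far from log-normal
  would be matched only in the two constrained tails.
- PAFs use one relative-risk curve per cause for all ages, sexes, races,
  and years.
- Pipeline stages run single-process; the per-(sex, race) model fits are
  independent and could be parallelized without changing results.
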