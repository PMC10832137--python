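# Methods

`fpgrid` estimates six family-planning indicators — contraceptive prevalence
rate (CPR), modern CPR (mCPR), traditional CPR (tCPR), unmet need for modern
methods, met need, and intention to use contraception — on a regular grid of
~5×5-km cells and at two administrative levels, from cluster-survey
microdata. This note records the model, the synthetic data-generating
process used for validation, the numerical choices, and what the tests do
and do not demonstrate.

## Indicators and the nested decomposition

The six indicators are mathematically interlocked (CPR = mCPR + tCPR;
met need = mCPR / (mCPR + unmet need)), so estimating them independently
cannot guarantee consistency. The package instead models four *nested*
conditional probabilities:

| symbol | population | outcome |
|---|---|---|
| p_any | all women 15–49 | currently using any contraceptive method |
| p_mod | users | using at least one modern method |
| p_need | non-users | in need of family planning |
| p_int | in-need non-users | intending future contraceptive use |

and recombines them, per posterior draw and per cell-year, into five
mutually exclusive groups

    A = (1 − p_any)(1 − p_need)          not in need
    B = (1 − p_any) p_need (1 − p_int)   in need, not using, no intent
    C = (1 − p_any) p_need p_int         in need, not using, intends
    D = p_any (1 − p_mod)                traditional methods only
    E = p_any p_mod                      modern methods

which sum to one algebraically. The final indicators are CPR = p_any,
mCPR = E, tCPR = D, unmet need = B + C + D, met need = E / (1 − A),
intention to use = p_int. Because recombination is applied to draws, never
to draw means, the identities hold exactly on every draw and the nonlinear
ones (met need) propagate uncertainty correctly. Met need is undefined
(NaN) where nobody is in need (A = 1 numerically); its aggregation weight
is zero there, so the NaN never enters an estimate.

**Need for family planning** is assigned by a decision tree over the
questionnaire: current users are in need; pregnant and postpartum-amenorrheic
(birth within 24 months) women are in need iff the (last) pregnancy was
unwanted or wanted later; remaining women are screened out as not in need if
not sexually active or infecund (reported markers — cannot have children,
menopause, hysterectomy, never menstruated — or married ≥ 5 years, never
used contraception and never gave birth, or last birth ≥ 5 years ago with no
period since before that birth); the rest are in need unless they want
a(nother) child within two years. Evaluation order is: use, pregnancy
branches, screens, preference; the tests check equivalence against an
order-free set-logic restatement on the exhaustive input cross product.
Modern methods are pills, condoms, diaphragm, spermicides/sponges, implants,
injections, IUDs, male/female sterilization, patches, rings and emergency
contraception; every other recognised method (rhythm, standard-days, LAM,
withdrawal, herbal, charms/amulets) is traditional, and unknown codes are
rejected rather than silently classified. "Unsure" answers to the intent
item count as not intending.

## Synthetic worlds

Real inputs (survey series, admin shapefiles, population rasters) are
emulated by a generator so that every stage is testable against known truth.

* **Geography.** An `nrows × ncols` grid of square cells (5 km default),
  partitioned into admin1 row bands, each split column-wise into admin2
  blocks — a trivially exhaustive, disjoint two-level hierarchy.
* **Population.** Women 15–49 per cell-year: a smooth lognormal surface
  scaled to a national total (2 million default) growing 1.5%/year.
* **Covariates.** Five surfaces per year — night-time lights, travel time to
  settlement, travel time to health facility, population (log of the
  raster), female education — generated as Gaussian-filtered noise with
  small per-year drift and standardised per year across cells.
* **Latent truth.** Each nested probability is logit-linear in the
  standardised covariates plus a separable space–time Gaussian process:
  Matérn-3/2 correlation in space (range 30 km, SD 0.4 logits by default)
  and stationary AR(1) across years (coefficient 0.85). Defaults put
  national CPR near 30%, the modern share of use near 0.9, need among
  non-users near 0.25 and intent near 0.55 — the operating range of the
  focus countries. With the spatial SD at zero the logit field equals the
  covariate predictor exactly (tested).
* **Surveys.** Clusters are grid cells drawn proportional to population
  (the design is therefore approximately self-weighting); design weights
  are lognormal noise (σ = 0.3), giving Kish effective sample sizes below
  the raw counts. Respondent outcomes are conditional Bernoulli draws from
  the cell's nested truths, and questionnaire fields are constructed to be
  exactly consistent with the derivation tree. Ever-married women get a
  +0.8-logit any-use offset, with the never-married offset solved by Newton
  so the population marginal still equals the latent field.
  Design features: GPS displacement (uniform direction, distance U(0,2) km
  for 99% of clusters, U(0,5) km for 1%, clamped at the border);
  polygon-only geocoding at admin1 or admin2; and three questionnaire
  restrictions — ever-married-only samples, missing need components
  (wantedness and fecundity items blanked; need is then derived with a
  preference-only partial definition), and a 12-month intent horizon
  (simulated as intent × Bernoulli(0.7)). Surveys without an intent item
  contribute no intent observations at all.

What the generator does **not** emulate: non-response and misreporting,
within-cluster correlation beyond the shared cell probability, secular
trends outside the covariate + AR1 class, urban/rural stratification, or
any real country's geography. Passing tests therefore demonstrate internal
statistical correctness of the pipeline under its own model class, not
performance on real survey data.

## From microdata to observations

Respondent flags are collapsed per cluster (point surveys) or per polygon
(polygon surveys) into binomial aggregates: survey-weighted prevalence
Σwᵢyᵢ/Σwᵢ over applicable respondents and Kish effective sample size
(Σw)²/Σw². Clusters with no applicable respondents emit nothing.

**Crosswalking.** For each restriction type and affected indicator
(ever-married-only → all four; missing-need → need and intent; horizon →
intent only), a crosswalk model is fitted from reference surveys where both
definitions are computable on the same microdata: the weighted mean logit
difference (full − restricted) with its residual variance. Restricted
observations are shifted by the coefficient on the logit scale, and their
effective sample size is deflated so that binomial variance plus crosswalk
residual variance (delta method) equals the adjusted total variance —
keeping the downstream binomial interface unchanged. The coefficient is a
single constant per restriction-indicator pair (no covariate dependence).
Prevalences at 0 or 1 receive a 1/(2 n_eff) continuity correction with a
warning.

**Polygon resampling.** The stage-2 model needs point data, so polygon
observations are resampled: up to `max_points` (default 100) cells drawn
without replacement proportional to population, each pseudo-point at a cell
center inheriting the parent prevalence and a population-proportional share
of the parent n_eff, renormalised to conserve the total exactly.

## Stage 1: stacked generalisation

Three sub-models are fitted per indicator to the binomial observations on
the five covariates: a B-spline additive logistic model (7 knots per
covariate, ridge-penalised), an L2 logistic regression with the penalty
chosen on an internal validation split, and gradient-boosted trees (depth 3,
learning rate 0.05, up to 200 trees with early stopping). Fractional
binomial outcomes are handled by weighted 0/1 row expansion. Out-of-fold
predictions come from 5-fold cross-validation blocked by the admin1 unit of
each observation (random folds are substituted, with a warning, only when
blocking would leave a fold with fewer than 10 training points). Full-data
refits produce the prediction surfaces. Zero-variance covariates are
dropped with a warning; degenerate outcomes fall back to an intercept-only
model.

## Stage 2: geostatistical model

Per country-indicator, observations i with prevalence p̂ᵢ and effective size
nᵢ contribute a continuous binomial log-likelihood
nᵢ[p̂ᵢ log πᵢ + (1−p̂ᵢ) log(1−πᵢ)] with

    logit πᵢ = b + Σₖ wₖ · logit(stacker surface k at the obs cell-year) + u(cell, year)

where w is a simplex (softmax-parameterised) and u is a latent Gaussian
field with separable covariance Σ_s ⊗ T + τ²I: Matérn-3/2 spatial
correlation Σ_s, and temporal covariance T = σ² AR1(φ) + σ_static² J —
an AR(1) component plus a time-constant component sharing the same spatial
correlation. The static component exists because persistent local error in
the covariate surfaces cannot be represented by a single AR(1) without
biasing its persistence estimate; without it the model demonstrably
understates the uncertainty of time-stable deviations. The nugget τ² is
i.i.d. at cell-year level, which keeps the latent dimension equal to
cells × years and the prior eigendecomposition exactly Kronecker.

Inference is empirical-Bayes Laplace:

1. **Weights** w by binomial ML on the out-of-fold stacker logits (honest
   relative weighting); the **intercept** b is then recalibrated against the
   full-data surfaces actually used for prediction, marginalising over the
   latent prior variance by Gauss–Hermite quadrature (the reported point
   estimate is a draw mean, i.e. E[expit(η+u)], which exceeds expit(η)
   below one half — calibrating b conditionally would bias the draw means).
2. **Hyperparameters** (range, σ, φ, τ, σ_static) by Gaussian marginal
   likelihood of the out-of-fold logit residuals with known heteroscedastic
   binomial measurement variances, initialised from a space–time variogram
   WLS fit and softly shrunk toward prior medians (range 50 km, σ 0.5,
   φ 0.8, τ 0.15, σ_static 0.15; quadratic penalty in transformed space).
   Residuals are out-of-fold because in-sample residuals against the
   flexible sub-models understate the field; polygon pseudo-points are
   excluded because they inherit their parent's prevalence and split n_eff,
   which misstates both their differences and their noise. The curvature of
   this likelihood gives an asymptotic hyperparameter covariance.
3. **The latent field** posterior mode by damped Newton at the plug-in
   hyperparameters. Solves use preconditioned conjugate gradients with the
   exact Kronecker eigendecomposition of the prior (never a dense
   precision), so a 20×20-cell × 8-year model solves in seconds.
4. **Draws** by perturbation sampling, x = mode + (Q+W)⁻¹(Q^{1/2}e₁ +
   W^{1/2}e₂), which has exactly the Gaussian-approximation covariance
   (Q+W)⁻¹. Hyperparameter uncertainty is propagated by splitting the draws
   into batches (8 by default), resampling the hyperparameters from their
   asymptotic normal distribution per batch and re-solving the mode.

Collapsing the SD priors to ~0 reduces predictions to the calibrated
stacker combination (tested as the fixed-effects limit). Countries and
indicators are fitted independently.

## Aggregation and reporting

Cell-level indicator draws aggregate to admin2, admin1 and national
estimates by weighted means with the denominator matching each indicator:
women 15–49 for CPR/mCPR/tCPR/unmet need; women in need, pop·(1−A), for met
need; in-need non-users, pop·(1−p_any)·p_need, for intention to use —
computed per draw where draw-dependent. Admin1 and national values are
aggregated directly from cells; equality with re-aggregated admin2 values is
kept as a test. Point estimates are draw means; 95% uncertainty intervals
are the empirical 2.5th/97.5th draw quantiles using the Hyndman–Fan type-8
(median-unbiased) estimator — at 50 draws the common linear-interpolation
rule places the 2.5% cut near ±1.79 posterior SDs instead of ±1.96, an
inward bias that materially distorts nominal coverage; at 1000 draws the
two rules agree to well under 0.1%. A change between two years (per-draw
difference × 100, in percentage points) is "statistically significant" when
the posterior probability of an increase is below 2.5% or above 97.5%.
Pearson correlations between indicators are computed over unit-level point
estimates. Percentages are reported to one decimal place.

## Validation and problem sizes

The central check is interval calibration: on 20 replicate synthetic worlds
(20×20 cells, 8 years, 4×2 admin units, 30 surveys of 30 clusters × 25
women with mixed point/displaced/polygon geocoding, 50 draws), the 95%
admin2 CPR intervals cover the true population-weighted admin2 prevalence
for 90–98% of the 1,280 unit-years. CPR depends only on the any-use model,
so the calibration replicates fit that model; the full four-model
recombination runs in the smoke-scale pipeline tests and the acceptance
script (10–12-cell grids, 3–4 years, 40–100 draws). Exhaustive oracles
back the need decision tree (full input cross product) and polygon
resampling (enumerated inclusion probabilities on a 6-cell polygon);
crosswalk recovery, conservation laws (group shares to 1e-12, n_eff to
1e-9, re-aggregation to 1e-12) and byte-level run determinism complete the
suite.

## Known limitations

* Inference is approximate: plug-in empirical-Bayes hyperparameters with
  asymptotic-normal resampling, a Laplace (Gaussian) field posterior, and
  no MCMC. Calibration sits near the lower edge of the accepted 90–98%
  band, reflecting residual underpropagation (e.g. stacker-surface error at
  unsampled cells).
* The crosswalk is a constant logit shift per restriction-indicator pair;
  heterogeneous or covariate-dependent definition gaps are out of scope.
* Polygon observations are converted to pseudo-points rather than modelled
  with an areal (polygon-integral) likelihood.
* The grid GMRF uses dense spatial eigendecomposition, practical to a few
  thousand cells; country-scale grids would need a sparse SPDE-type
  representation.
* Synthetic-world caveats above: results certify the pipeline, not
  real-data performance.
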