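# fpgrid

Small-area estimation of family-planning indicators from cluster-survey
microdata, on a ~5×5-km grid and at two administrative levels, with full
uncertainty propagation.

Country-level statistics on contraceptive use hide large subnational
differences: a country with moderate national coverage can contain districts
where almost no women use modern methods. `fpgrid` is for quantitative
epidemiologists and demographers who want district-level time series of six
linked indicators — contraceptive prevalence rate (CPR), modern CPR (mCPR),
traditional CPR (tCPR), unmet need for modern methods, met need, and
intention to use contraception — estimated jointly so that the identities
between them hold exactly.

## The model

Rather than modelling six correlated indicators separately, `fpgrid` models
four *nested* conditional probabilities — any use among all women
(p_any), modern use among users (p_mod), need among non-users
(p_need), intention among in-need non-users (p_int) — and recombines
them per posterior draw into five exhaustive groups

    A = (1−p_any)(1−p_need)     B = (1−p_any)·p_need·(1−p_int)
    C = (1−p_any)·p_need·p_int  D = p_any·(1−p_mod)   E = p_any·p_mod

giving CPR = p_any, mCPR = E, tCPR = D, unmet need = B+C+D,
met need = E/(1−A), intention = p_int, with CPR ≡ mCPR + tCPR and
met need ≡ mCPR/(mCPR + unmet need) by construction.

Each nested probability is estimated in two stages from cluster-level
binomial aggregates (survey-weighted prevalence, Kish effective sample
size): a stacked-generalisation ensemble (spline additive model, ridge
logistic regression, boosted trees) on five covariate surfaces, followed by
a Bayesian geostatistical model whose logit-linear predictor combines the
stacker surfaces through simplex weights and adds a separable space–time
Gaussian field (Matérn-3/2 in space; AR(1) plus a time-constant component
in time; cell-year nugget), fitted by an empirical-Bayes Laplace
approximation with exact Kronecker algebra. Posterior draws propagate
through recombination and population-weighted aggregation (with
indicator-specific denominators) to admin estimates, changes over time with
significance calls, and indicator correlations.

Survey heterogeneity is handled explicitly: polygon-geocoded surveys are
resampled to population-weighted pseudo-points; surveys restricted to
ever-married women, missing need components, or asking intent on a 12-month
horizon are adjusted by crosswalk models fitted from reference surveys,
with their effective sample sizes deflated to carry the extra uncertainty.

A `synthetic_world` generator builds test countries — grid geography, admin
hierarchy, population and covariate rasters, latent truth, and surveys with
realistic design features (PPS cluster sampling, noisy weights, GPS
displacement, questionnaire restrictions) — so every stage is validated
against known truth. See `docs/methods.md` for the complete model
description and its limitations.

## Worked example

```bash
fpgrid run-all --seed 5 --n-draws 40 --out runs/demo
```

runs the full pipeline on the default synthetic world (here a 10×10-cell
grid, 3 years, 8 surveys of which half carry a questionnaire restriction)
and writes `estimates.csv`, `changes.csv`, `correlations.csv`, surface
summaries and a run manifest. The national rows of `estimates.csv` for the
final year:

```
       indicator     mean    lower    upper
             CPR 0.428881 0.405138 0.458807
            mCPR 0.389653 0.365415 0.415090
            tCPR 0.039228 0.032295 0.046902
      unmet_need 0.229537 0.209995 0.253699
        met_need 0.629298 0.595948 0.657607
intention_to_use 0.521792 0.471222 0.559937
```

Read: an estimated 42.9% (95% interval 40.5–45.9%) of women 15–49 use some
contraceptive method, 39.0% a modern method; 23.0% of all women have an
unmet need for modern methods, and 62.9% of women in need have that need
met. The identities hold (0.3897 + 0.0392 = 0.4289; 0.3897/(0.3897+0.2295)
= 0.629), and the estimate brackets this world's known truth (CPR 42.3%).
The change table reports, e.g., a −4.9 PPT (−7.8 to −1.9) decline in unmet
need over the three years, flagged statistically significant because more
than 97.5% of draws decreased.

The same stages are available individually (`simulate`, `prepare`, `fit`,
`predict`, `aggregate`, `report`) and as a Python API
(`fpgrid.run_pipeline`, `fpgrid.run_estimation`, and the per-stage
functions).

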