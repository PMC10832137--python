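"""Stage-2 geostatistical model: degenerate limits, information
monotonicity, draw consistency and determinism, hyperparameter recovery."""

import numpy as np
import pytest
from scipy.special import expit, logit

from fpgrid import GeostatPriors, draw_surfaces, fit_geostat, predict_mode
from fpgrid.geostat import (build_prior_eig, fit_ml_hyperparameters,
                            fit_simplex_weights, _transform)
from fpgrid.world import make_geography, matern32


@pytest.fixture(scope="module")
def geo():
    return make_geography(6, 6, cell_km=5.0, n_admin1=2, admin2_per_admin1=2)


def _simulate_obs(geo, rng, n_years=3, n_obs=120, n_trials=40.0,
                  field_sd=0.0, b0=0.0):
    """Observations generated from a known logit surface (optionally + GP)."""
    surface = expit(b0 + 0.8 * rng.standard_normal((n_years, geo.n_cells)))
    surfaces = np.stack([surface, np.clip(surface + 0.02, 0.01, 0.99),
                         np.clip(surface - 0.02, 0.01, 0.99)])
    cells = rng.integers(0, geo.n_cells, n_obs)
    tix = rng.integers(0, n_years, n_obs)
    eta = logit(surface)[tix, cells]
    if field_sd > 0:
        eta = eta + rng.normal(0, field_sd, n_obs)
    prev = rng.binomial(int(n_trials), expit(eta)) / n_trials
    n_eff = np.full(n_obs, n_trials)
    oof_logit = logit(surfaces)[:, tix, cells].T
    return cells, tix, prev, n_eff, oof_logit, surfaces


def _tight_priors(scale=1e-6):
    """Priors that collapse every variance component of the field."""
    return GeostatPriors(sd_bounds=(scale / 10, scale),
                         nugget_bounds=(scale / 10, scale),
                         static_bounds=(scale / 10, scale),
                         sd_median=scale, nugget_median=scale,
                         static_median=scale)


class TestFitGeostat:
    def test_degenerate_field_limit_returns_stacker_combination(self, geo, rng):
        """With all field variances collapsed to ~0, posterior-mode
        predictions equal the calibrated simplex-weighted stacker surface."""
        cells, tix, prev, n_eff, oof, surfaces = _simulate_obs(geo, rng)
        fit = fit_geostat(cells, tix, prev, n_eff, oof, surfaces, geo, 3,
                          priors=_tight_priors())
        assert abs(fit.mode).max() < 1e-4
        expected = expit(fit.intercept
                         + np.tensordot(fit.weights, logit(surfaces), axes=(0, 0)))
        np.testing.assert_allclose(predict_mode(fit), expected, atol=1e-4)
        # the data were generated from the surface itself: near-zero intercept
        assert abs(fit.intercept) < 0.1

    def test_doubling_information_shrinks_posterior_sd(self, geo, rng):
        """A single observed cell: doubling its effective sample size shrinks
        the posterior SD of that cell's prediction."""
        n_years = 2
        surfaces = np.full((3, n_years, geo.n_cells), 0.35)
        cells = np.array([7])
        tix = np.array([0])
        oof = logit(surfaces)[:, tix, cells].T
        sds = []
        for n in (25.0, 50.0):
            fit = fit_geostat(cells, tix, np.array([0.5]), np.array([n]),
                              oof, surfaces, geo, n_years)
            d = draw_surfaces(fit, 600, seed=3, hyper_uncertainty=False)
            sds.append(d[:, 0, 7].std())
        assert sds[1] < sds[0]

    def test_observations_outside_grid_or_years_rejected(self, geo, rng):
        cells, tix, prev, n_eff, oof, surfaces = _simulate_obs(geo, rng)
        with pytest.raises(ValueError, match="grid"):
            fit_geostat(cells + geo.n_cells, tix, prev, n_eff, oof, surfaces,
                        geo, 3)
        with pytest.raises(ValueError, match="year"):
            fit_geostat(cells, tix + 10, prev, n_eff, oof, surfaces, geo, 3)

    def test_no_observations_rejected(self, geo):
        surfaces = np.full((3, 2, geo.n_cells), 0.4)
        with pytest.raises(ValueError, match="at least one"):
            fit_geostat(np.array([], int), np.array([], int), np.array([]),
                        np.array([]), np.empty((0, 3)), surfaces, geo, 2)


class TestDrawSurfaces:
    def test_draw_mean_tracks_mode_prediction(self, geo, rng):
        cells, tix, prev, n_eff, oof, surfaces = _simulate_obs(
            geo, rng, field_sd=0.3)
        fit = fit_geostat(cells, tix, prev, n_eff, oof, surfaces, geo, 3)
        draws = draw_surfaces(fit, 1000, seed=5, hyper_uncertainty=False)
        pm = predict_mode(fit)
        mc_se = draws.std(axis=0) / np.sqrt(1000)
        # mode vs mean of the transformed Gaussian differ by the Jensen term;
        # allow it on top of Monte-Carlo error
        assert np.nanmax(np.abs(draws.mean(axis=0) - pm)
                         - (4 * mc_se + 0.01)) < 0

    def test_zero_variance_posterior_gives_identical_draws(self, geo, rng):
        cells, tix, prev, n_eff, oof, surfaces = _simulate_obs(geo, rng)
        fit = fit_geostat(cells, tix, prev, n_eff, oof, surfaces, geo, 3,
                          priors=_tight_priors())
        draws = draw_surfaces(fit, 10, seed=6, hyper_uncertainty=False)
        assert draws.std(axis=0).max() < 1e-3

    def test_draws_strictly_inside_unit_interval(self, geo, rng):
        cells, tix, prev, n_eff, oof, surfaces = _simulate_obs(geo, rng)
        fit = fit_geostat(cells, tix, prev, n_eff, oof, surfaces, geo, 3)
        draws = draw_surfaces(fit, 50, seed=7)
        assert (draws > 0).all() and (draws < 1).all()

    def test_same_seed_identical_draws(self, geo, rng):
        cells, tix, prev, n_eff, oof, surfaces = _simulate_obs(geo, rng)
        fit = fit_geostat(cells, tix, prev, n_eff, oof, surfaces, geo, 3)
        a = draw_surfaces(fit, 24, seed=8)
        b = draw_surfaces(fit, 24, seed=8)
        np.testing.assert_array_equal(a, b)

    def test_fewer_than_two_draws_rejected(self, geo, rng):
        cells, tix, prev, n_eff, oof, surfaces = _simulate_obs(geo, rng)
        fit = fit_geostat(cells, tix, prev, n_eff, oof, surfaces, geo, 3)
        with pytest.raises(ValueError):
            draw_surfaces(fit, 1, seed=9)


class TestSimplexWeights:
    def test_weights_form_simplex(self, rng):
        oof = rng.normal(0, 1, (200, 3))
        prev = expit(oof[:, 0] + rng.normal(0, 0.2, 200))
        w, b = fit_simplex_weights(oof, prev, np.full(200, 30.0))
        assert w.min() >= 0
        assert w.sum() == pytest.approx(1.0)

    def test_perfect_submodel_dominates(self, rng):
        n = 600
        eta = rng.normal(0, 1.2, n)
        oof = np.column_stack([eta, rng.normal(0, 1.2, n),
                               rng.normal(0, 1.2, n)])
        prev = rng.binomial(80, expit(eta)) / 80.0
        w, _ = fit_simplex_weights(oof, prev, np.full(n, 80.0))
        assert w[0] > 0.8


class TestHyperparameterRecovery:
    def test_ml_recovers_field_parameters_within_intervals(self):
        """Gaussian residuals simulated from the model (known range, SD, AR1,
        nugget): the marginal-likelihood estimates cover the truth in at
        least 8 of 10 replicate 95% intervals for range and SD."""
        geo = make_geography(15, 15, cell_km=5.0)
        true = {"range_km": 30.0, "spatial_sd": 0.5, "ar1": 0.8,
                "nugget_sd": 0.2, "static_sd": 0.2}
        n_years, n_obs = 6, 350
        eig_s, eig_t, lam = build_prior_eig(geo, n_years, true["range_km"],
                                            true["spatial_sd"], true["ar1"],
                                            true["nugget_sd"], true["static_sd"])
        Vs, _ = eig_s
        Vt, _ = eig_t
        priors = GeostatPriors(penalty=0.1)
        hits = {"log_range": 0, "log_sd": 0}
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            z = rng.standard_normal((geo.n_cells, n_years))
            field = Vs @ (np.sqrt(lam) * (Vs.T @ z @ Vt)) @ Vt.T
            cells = rng.integers(0, geo.n_cells, n_obs)
            tix = rng.integers(0, n_years, n_obs)
            meas_sd = 0.25
            resid = field[cells, tix] + rng.normal(0, meas_sd, n_obs)
            meas_var = np.full(n_obs, meas_sd ** 2)
            xy = geo.cell_centers()[cells]
            hyper, theta, cov = fit_ml_hyperparameters(
                xy, tix, cells, resid, meas_var, priors, seed=rep)
            assert cov is not None
            se = np.sqrt(np.diag(cov))
            t_true = _transform(true["range_km"], true["spatial_sd"],
                                true["ar1"], true["nugget_sd"],
                                true["static_sd"])
            if abs(theta[0] - t_true[0]) < 1.96 * se[0]:
                hits["log_range"] += 1
            if abs(theta[1] - t_true[1]) < 1.96 * se[1]:
                hits["log_sd"] += 1
        assert hits["log_range"] >= 8
        assert hits["log_sd"] >= 8


def test_prior_eig_reconstructs_covariance(geo):
    """The Kronecker eigendecomposition reproduces the dense prior covariance
    on a small grid."""
    (Vs, _), (Vt, _), lam = build_prior_eig(geo, 3, 20.0, 0.5, 0.7, 0.1, 0.2)
    xy = geo.cell_centers()
    d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
    idx = np.arange(3)
    T = 0.25 * 0.7 ** np.abs(idx[:, None] - idx[None, :]) + 0.04
    dense = np.kron(matern32(d, 20.0), T) + 0.01 * np.eye(geo.n_cells * 3)
    K = np.kron(Vs, Vt)
    recon = K @ np.diag(lam.ravel()) @ K.T
    np.testing.assert_allclose(recon, dense, atol=1e-8)
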