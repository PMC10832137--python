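"""Synthetic world generator: geography invariants, determinism, degenerate
GP limit, the Matern variogram of simulated fields, and the survey
simulator's design features and sampling distribution."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit, logit

from fpgrid import (SurveyDesignSpec, WorldConfig, generate_world, matern32,
                    simulate_survey)
from fpgrid.world import make_geography, NESTED_INDICATORS


class TestGeography:
    def test_partition_exhaustive_and_disjoint(self):
        geo = make_geography(10, 12, n_admin1=3, admin2_per_admin1=2)
        assert geo.admin2_of_cell.shape == (120,)
        # every cell in exactly one admin2, every admin2 in exactly one admin1
        assert set(geo.admin2_of_cell) == set(range(6))
        assert len(geo.admin1_of_admin2) == 6
        sizes = [len(geo.cells_in_admin2(u)) for u in range(6)]
        assert sum(sizes) == 120 and min(sizes) > 0
        for u1 in range(3):
            cells = geo.cells_in_admin1(u1)
            a2s = set(geo.admin2_of_cell[cells])
            assert a2s == set(np.flatnonzero(geo.admin1_of_admin2 == u1))

    @pytest.mark.parametrize("kw", [
        dict(nrows=3, ncols=10),
        dict(nrows=10, ncols=10, n_admin1=1),
        dict(nrows=10, ncols=10, admin2_per_admin1=1),
    ])
    def test_invalid_configurations_rejected(self, kw):
        with pytest.raises(ValueError):
            make_geography(**{"nrows": 10, "ncols": 10, **kw})

    def test_cell_of_xy_roundtrip(self):
        geo = make_geography(6, 7)
        centers = geo.cell_centers()
        got = geo.cell_of_xy(centers[:, 0], centers[:, 1])
        np.testing.assert_array_equal(got, np.arange(geo.n_cells))


class TestGenerateWorld:
    def test_same_seed_bitwise_identical(self):
        cfg = WorldConfig(nrows=8, ncols=8, n_admin1=2, admin2_per_admin1=2,
                          years=(2000, 2001), seed=11)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        for k in NESTED_INDICATORS:
            np.testing.assert_array_equal(w1.true_fields[k], w2.true_fields[k])
        np.testing.assert_array_equal(w1.population, w2.population)
        np.testing.assert_array_equal(w1.covariates, w2.covariates)

    def test_zero_spatial_sd_gives_pure_linear_predictor(self):
        cfg = WorldConfig(nrows=8, ncols=8, n_admin1=2, admin2_per_admin1=2,
                          years=(2000, 2001), seed=3)
        for fp in cfg.field_params.values():
            fp.spatial_sd = 0.0
        w = generate_world(cfg)
        for k in NESTED_INDICATORS:
            np.testing.assert_allclose(logit(w.true_fields[k]),
                                       w.linear_predictor[k], atol=1e-10)

    def test_noncontiguous_years_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            WorldConfig(years=(2000, 2002, 2004))

    def test_population_positive_and_grows(self, small_world):
        assert (small_world.population >= 0).all()
        totals = small_world.population.sum(axis=1)
        assert (np.diff(totals) > 0).all()

    def test_probabilities_strictly_inside_unit_interval(self, small_world):
        for k in NESTED_INDICATORS:
            v = small_world.true_fields[k]
            assert (v > 0).all() and (v < 1).all()

    def test_empirical_variogram_matches_matern(self):
        """Average semivariogram of single-year GP fields over 100 seeds
        matches the closed-form Matern-3/2 curve at the set range."""
        rng_km, sd = 25.0, 0.5
        n_seeds = 100
        base = WorldConfig(nrows=12, ncols=12, n_admin1=2, admin2_per_admin1=2,
                           years=(2000,), seed=0)
        for fp in base.field_params.values():
            fp.spatial_range_km = rng_km
            fp.spatial_sd = sd
        geo = generate_world(base).geo
        xy = geo.cell_centers()
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        iu, ju = np.triu_indices(geo.n_cells, k=1)
        bins = [(2.5, 7.5), (7.5, 15.0), (15.0, 25.0), (25.0, 40.0)]
        acc = np.zeros(len(bins))
        for s in range(n_seeds):
            w = generate_world(dataclasses.replace(base, seed=s))
            # the GP realisation: logit truth minus the covariate predictor
            resid = (logit(w.true_fields["any_use"][0])
                     - w.linear_predictor["any_use"][0])
            g = 0.5 * (resid[iu] - resid[ju]) ** 2
            for b, (lo, hi) in enumerate(bins):
                m = (d[iu, ju] > lo) & (d[iu, ju] <= hi)
                acc[b] += g[m].mean()
        acc /= n_seeds
        for b, (lo, hi) in enumerate(bins):
            m = (d[iu, ju] > lo) & (d[iu, ju] <= hi)
            href = d[iu, ju][m].mean()
            expected = sd ** 2 * (1.0 - matern32(href, rng_km))
            assert acc[b] == pytest.approx(expected, rel=0.25, abs=0.004)


class TestSimulateSurvey:
    def test_unrestricted_point_survey_fully_populated(self, small_world):
        d = SurveyDesignSpec(year=2000, n_clusters=5, respondents_per_cluster=10)
        m = simulate_survey(small_world, d, seed=1)
        assert len(m) == 50
        assert m["x_km"].notna().all() and m["y_km"].notna().all()
        assert (m["pregnancy_status"] != "").all()
        assert (m["fertility_pref"] != "").all()
        assert (m["weight"] > 0).all()

    def test_ever_married_only_restriction(self, small_world):
        d = SurveyDesignSpec(year=2000, n_clusters=10,
                             respondents_per_cluster=20, ever_married_only=True)
        m = simulate_survey(small_world, d, seed=2)
        assert m["ever_married"].all()
        assert len(m) < 200  # never-married respondents absent, not zero-filled

    def test_contradictory_intent_flags_rejected(self):
        with pytest.raises(ValueError):
            SurveyDesignSpec(year=2000, intent_12m_horizon=True,
                             no_intent_question=True)

    def test_year_outside_range_rejected(self, small_world):
        d = SurveyDesignSpec(year=1995)
        with pytest.raises(ValueError, match="outside"):
            simulate_survey(small_world, d, seed=0)

    def test_polygon_mode_drops_coordinates(self, small_world):
        d = SurveyDesignSpec(year=2000, geocoding="polygon-admin2")
        m = simulate_survey(small_world, d, seed=3)
        assert m["x_km"].isna().all()
        assert (m["polygon_level"] == "admin2").all()
        assert (m["polygon_id"] == m["admin2_id"]).all()

    def test_displacement_bounded_and_inside_country(self, small_world):
        d = SurveyDesignSpec(year=2000, n_clusters=200,
                             respondents_per_cluster=1,
                             geocoding="displaced-point")
        m = simulate_survey(small_world, d, seed=4)
        ext_x, ext_y = small_world.geo.extent_km()
        assert (m["x_km"] >= 0).all() and (m["x_km"] < ext_x).all()
        assert (m["y_km"] >= 0).all() and (m["y_km"] < ext_y).all()
        centers = small_world.geo.cell_centers()[m["cell_true"]]
        dist = np.hypot(m["x_km"] - centers[:, 0], m["y_km"] - centers[:, 1])
        assert (dist <= 5.0 + 1e-9).all()

    def test_weighted_prevalence_matches_constant_truth(self):
        """500 clusters x 30 women on a constant-truth world: weighted any-use
        prevalence within 3 Monte-Carlo SEs of the set truth."""
        cfg = WorldConfig(nrows=8, ncols=8, n_admin1=2, admin2_per_admin1=2,
                          years=(2000,), seed=9)
        p_true = 0.3
        for name, fp in cfg.field_params.items():
            fp.spatial_sd = 0.0
            fp.betas = (0.0,) * 5
            fp.intercept = float(logit(p_true)) if name == "any_use" else fp.intercept
        w = generate_world(cfg)
        np.testing.assert_allclose(w.true_fields["any_use"], p_true, atol=1e-12)
        d = SurveyDesignSpec(year=2000, n_clusters=500, respondents_per_cluster=30)
        m = simulate_survey(w, d, seed=10)
        using = (m["current_method"] != "").astype(float)
        est = (m["weight"] * using).sum() / m["weight"].sum()
        n_eff = m["weight"].sum() ** 2 / (m["weight"] ** 2).sum()
        se = np.sqrt(p_true * (1 - p_true) / n_eff)
        assert abs(est - p_true) < 3 * se

    def test_conditional_structure_converges(self, small_world):
        """Among users the modern fraction, and among non-users the in-need
        fraction, track the cells' conditional truths at large n."""
        d = SurveyDesignSpec(year=2001, n_clusters=400, respondents_per_cluster=30)
        m = simulate_survey(small_world, d, seed=12)
        t = 1
        users = m[m["current_method"] != ""]
        modern_truth = small_world.true_fields["modern_among_users"][t]
        frac_modern = users["current_method"].isin(
            ("pills", "condoms", "implant", "injection", "iud",
             "female_sterilization")).mean()
        expected = modern_truth[users["cell_true"]].mean()
        assert frac_modern == pytest.approx(expected, abs=0.02)

        from fpgrid import derive_flags_frame
        df = derive_flags_frame(m)
        nonusers = df[df["flag_any_use"] == 0]
        need_truth = small_world.true_fields["need_among_nonusers"][t]
        assert nonusers["flag_need_among_nonusers"].mean() == pytest.approx(
            need_truth[nonusers["cell_true"]].mean(), abs=0.02)

    def test_same_seed_identical_survey(self, small_world):
        d = SurveyDesignSpec(year=2000)
        a = simulate_survey(small_world, d, seed=5)
        b = simulate_survey(small_world, d, seed=5)
        import pandas as pd
        pd.testing.assert_frame_equal(a, b)
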