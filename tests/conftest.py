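import dataclasses

import numpy as np
import pytest

from fpgrid import (PipelineConfig, SurveyDesignSpec, WorldConfig,
                    default_survey_plan, generate_world, simulate_survey)


@pytest.fixture(scope="session")
def small_world():
    """10x10-cell, 3-year world with 2x2 admin units; session-scoped."""
    cfg = WorldConfig(nrows=10, ncols=10, n_admin1=2, admin2_per_admin1=2,
                      years=tuple(range(2000, 2003)), seed=42)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_micro(small_world):
    """One unrestricted point-located survey on the small world."""
    design = SurveyDesignSpec(year=2001, n_clusters=25, respondents_per_cluster=25)
    return simulate_survey(small_world, design, seed=7, survey_id="SVY000_2001")


@pytest.fixture(scope="session")
def smoke_pipeline_config():
    """Tiny full-pipeline configuration (all four indicators, 40 draws)."""
    wcfg = WorldConfig(nrows=10, ncols=10, n_admin1=2, admin2_per_admin1=2,
                       years=tuple(range(2000, 2003)), seed=5)
    surveys = default_survey_plan(wcfg.years, n_surveys=8, restricted_fraction=0.5)
    return PipelineConfig(world=wcfg, surveys=surveys, n_draws=40, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_record(**kw):
    """A fully-populated fecund, sexually active non-user record."""
    rec = {
        "age": 30, "ever_married": True, "current_method": "",
        "pregnancy_status": "neither", "wantedness": "",
        "fertility_pref": "wants_within_2y", "sexually_active": True,
        "cannot_have_children": False, "menopausal": False,
        "hysterectomy": False, "never_menstruated": False,
        "years_married": 2.0, "ever_used_contraception": True,
        "ever_gave_birth": True, "years_since_last_birth": 1.0,
        "period_since_last_birth": True, "intent_any": "", "intent_12m": "",
        "weight": 1.0,
    }
    rec.update(kw)
    return rec


@pytest.fixture()
def record_factory():
    return make_record
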