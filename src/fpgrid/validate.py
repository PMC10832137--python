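"""Simulation-based validation experiments.

The central check on the whole estimation chain is interval calibration:
on synthetic worlds with known truth, the 95% uncertainty intervals of the
admin2 estimates should cover the true population-weighted admin2 prevalence
close to 95% of the time.  Approximate inference (stacking + plug-in
hyperparameters + Laplace draws) is accepted inside a 90-98% band.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .aggregate import draw_quantile

from .pipeline import (PipelineConfig, default_survey_plan, run_estimation,
                       simulate_microdata)
from .world import WorldConfig, generate_world


@dataclass
class CoverageResult:
    covered: int
    total: int
    per_replicate: list[float]

    @property
    def coverage(self) -> float:
        return self.covered / self.total


def coverage_config(seed: int = 0, n_surveys: int = 30,
                    n_draws: int = 50) -> PipelineConfig:
    """Study conditions for the calibration experiment: 20x20 grid of 5-km
    cells, 8 years, 30 mixed-geocoding unrestricted surveys, 50 draws."""
    world = WorldConfig(nrows=20, ncols=20, n_admin1=4, admin2_per_admin1=2,
                        years=tuple(range(2000, 2008)), seed=seed)
    surveys = default_survey_plan(world.years, n_surveys=n_surveys,
                                  restricted_fraction=0.0)
    return PipelineConfig(world=world, surveys=surveys,
                          indicators=("any_use",), n_draws=n_draws, seed=seed)


def admin2_cpr_coverage(n_replicates: int = 20, seed: int = 0,
                        n_surveys: int = 30, n_draws: int = 50) -> CoverageResult:
    """Fraction of admin2 unit-years whose 95% interval covers the true
    admin2 CPR, pooled over seeded replicate worlds."""
    covered = total = 0
    per_rep = []
    for r in range(n_replicates):
        rep_seed = seed + 1000 * r
        cfg = coverage_config(seed=rep_seed, n_surveys=n_surveys, n_draws=n_draws)
        world = generate_world(dataclasses.replace(cfg.world, seed=rep_seed))
        micro = simulate_microdata(world, cfg.surveys, seed=rep_seed + 100)
        res = run_estimation(world, micro, cfg)
        agg = res["unit_draws"][("CPR", "admin2")]       # (n_draws, n_years, n_units)
        lower = draw_quantile(agg, 2.5, axis=0)
        upper = draw_quantile(agg, 97.5, axis=0)
        truth = world.true_admin_mean("any_use", "admin2")  # (n_years, n_units)
        hit = (truth >= lower) & (truth <= upper)
        covered += int(hit.sum())
        total += hit.size
        per_rep.append(float(hit.mean()))
    return CoverageResult(covered, total, per_rep)
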