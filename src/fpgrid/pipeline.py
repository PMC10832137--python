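"""End-to-end orchestration: synthetic world -> microdata -> cluster
observations -> crosswalk -> polygon resampling -> stacking -> geostatistical
fit -> posterior draws -> recombination -> population-weighted estimates.

Every stage seeds its own generator deterministically from the run seed, so
a run is reproducible byte-for-byte.  Artifacts are written to a run
directory: microdata and observation CSVs, crosswalk models as JSON,
estimate/change/correlation CSVs, draw summary surfaces as NPZ, and a JSON
manifest echoing the configuration, seeds, library versions and stage
timings.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from . import __version__
from .aggregate import (aggregate_draws, change_over_time, changes_frame,
                        correlate, denominator_weights, draw_quantile,
                        summarize_estimates, _unit_ids)
from .crosswalk import (RESTRICTION_TYPES, crosswalk_observations,
                        fit_crosswalk_models)
from .geostat import GeostatPriors, draw_surfaces, fit_geostat
from .indicators import NESTED_INDICATORS, collapse_clusters, derive_flags_frame
from .recombine import recombine_draws
from .resample import resample_observations
from .stacking import StackerConfig, fit_stackers, predict_stackers
from .world import (SurveyDesignSpec, World, WorldConfig, config_to_dict,
                    generate_world, simulate_survey)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    surveys: list[SurveyDesignSpec] = field(default_factory=list)
    indicators: tuple[str, ...] = NESTED_INDICATORS
    n_draws: int = 1000
    max_resample_points: int = 100
    skip_crosswalk: bool = False
    stacker: StackerConfig = field(default_factory=StackerConfig)
    priors: GeostatPriors = field(default_factory=GeostatPriors)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.surveys:
            self.surveys = default_survey_plan(self.world.years)


def default_survey_plan(years: tuple[int, ...], n_surveys: int | None = None,
                        restricted_fraction: float = 0.0) -> list[SurveyDesignSpec]:
    """A survey plan cycling years and geocoding modes; optionally a fraction
    of surveys carries one questionnaire restriction each (round-robin)."""
    if n_surveys is None:
        n_surveys = max(2 * len(years), 8)
    modes = ("point", "point", "displaced-point", "polygon-admin2")
    restrictions = ("ever_married_only", "missing_need_components",
                    "intent_12m_horizon", "no_intent_question")
    plan = []
    n_restricted = int(round(restricted_fraction * n_surveys))
    for i in range(n_surveys):
        kw = {"year": years[i % len(years)], "geocoding": modes[i % len(modes)]}
        if i < n_restricted:
            kw[restrictions[i % len(restrictions)]] = True
        plan.append(SurveyDesignSpec(**kw))
    return plan


def simulate_microdata(world: World, surveys: list[SurveyDesignSpec],
                       seed: int) -> pd.DataFrame:
    """Simulate and concatenate all surveys in the plan (deterministic)."""
    frames = []
    for i, design in enumerate(surveys):
        sid = f"SVY{i:03d}_{design.year}"
        frames.append(simulate_survey(world, design, seed=seed + 101 * i + 7,
                                      survey_id=sid))
    return pd.concat(frames, ignore_index=True)


def prepare_observations(world: World, micro: pd.DataFrame,
                         cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Flags -> cluster collapse -> crosswalk -> polygon resampling."""
    flagged = derive_flags_frame(micro)
    obs_parts = []
    for indicator in cfg.indicators:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_parts.append(collapse_clusters(flagged, indicator))
    obs = pd.concat(obs_parts, ignore_index=True)

    models = {}
    if not cfg.skip_crosswalk:
        present = set()
        for tag in obs["tags"].fillna(""):
            for r in RESTRICTION_TYPES:
                if r in tag:
                    present.add(r)
        if present:
            micro_by_survey = {sid: g for sid, g in micro.groupby("survey_id")}
            models = fit_crosswalk_models(micro_by_survey, present)
            obs = crosswalk_observations(obs, models)

    obs = resample_observations(obs, world.geo, world.population, world.years,
                                seed=cfg.seed + 5001,
                                max_points=cfg.max_resample_points)
    return obs, models


def fit_indicator(world: World, obs: pd.DataFrame, indicator: str,
                  cfg: PipelineConfig) -> tuple:
    """Stage-1 stacking + stage-2 geostatistical fit for one nested indicator."""
    sub = obs[obs["indicator"] == indicator].reset_index(drop=True)
    if len(sub) == 0:
        raise RuntimeError(f"no observations for indicator {indicator}")
    geo = world.geo
    cells = geo.cell_of_xy(sub["x_km"].to_numpy(), sub["y_km"].to_numpy())
    tix = sub["year"].to_numpy(int) - world.years[0]
    prev = sub["prevalence"].to_numpy(float)
    n_eff = sub["n_eff"].to_numpy(float)

    X = world.covariates[:, tix, cells].T
    blocks = geo.admin1_of_cell[cells]
    k = list(NESTED_INDICATORS).index(indicator)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ensemble = fit_stackers(X, prev, n_eff, blocks, cfg.stacker,
                                seed=cfg.seed + 11000 + k)
        surfaces = predict_stackers(ensemble, world.covariates)
    parent = sub["parent_id"].fillna("").to_numpy(dtype=object) \
        if "parent_id" in sub.columns else None
    fit = fit_geostat(cells, tix, prev, n_eff, logit(ensemble.oof_pred),
                      surfaces, geo, world.n_years, cfg.priors,
                      seed=cfg.seed + 12000 + k, pair_group=parent)
    return ensemble, fit


def run_estimation(world: World, micro: pd.DataFrame,
                   cfg: PipelineConfig) -> dict:
    """Run every modelling stage in memory and return all results."""
    timings = {}
    t0 = time.perf_counter()
    try:
        obs, models = prepare_observations(world, micro, cfg)
    except Exception as e:
        raise RuntimeError(f"stage 'prepare' failed: {e}") from e
    timings["prepare"] = time.perf_counter() - t0

    draws: dict[str, np.ndarray] = {}
    fits = {}
    for indicator in cfg.indicators:
        t0 = time.perf_counter()
        k = list(NESTED_INDICATORS).index(indicator)
        try:
            ensemble, fit = fit_indicator(world, obs, indicator, cfg)
            fits[indicator] = fit
            draws[indicator] = draw_surfaces(fit, cfg.n_draws,
                                             seed=cfg.seed + 13000 + k)
        except Exception as e:
            raise RuntimeError(f"stage 'fit_{indicator}' failed: {e}") from e
        timings[f"fit_{indicator}"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results = {"observations": obs, "crosswalk_models": models,
               "fits": fits, "nested_draws": draws, "timings": timings}

    if set(cfg.indicators) == set(NESTED_INDICATORS):
        groups, indicator_draws = recombine_draws(draws)
    elif "any_use" in cfg.indicators:
        groups, indicator_draws = None, {"CPR": draws["any_use"]}
    else:
        groups, indicator_draws = None, {}
    results["groups"] = groups
    results["indicator_draws"] = indicator_draws

    estimates, unit_draws_store = [], {}
    for name, vals in indicator_draws.items():
        if groups is not None:
            w = denominator_weights(name, world.population, nested=draws,
                                    groups=groups)
        else:
            w = world.population
        for level in ("admin2", "admin1", "national"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                agg = aggregate_draws(vals, w, world.geo, level)
            unit_draws_store[(name, level)] = agg
            den = _unit_weight_totals(w, world.geo, level)
            estimates.append(summarize_estimates(agg, name, level, world.years, den))
    results["estimates"] = (pd.concat(estimates, ignore_index=True)
                            if estimates else pd.DataFrame())
    results["unit_draws"] = unit_draws_store

    y0, y1 = world.years[0], world.years[-1]
    changes = []
    for (name, level), agg in unit_draws_store.items():
        changes.extend(change_over_time(agg, world.years, name, level, y0, y1))
    results["changes"] = changes_frame(changes) if changes else pd.DataFrame()

    corr_rows = []
    est = results["estimates"]
    if len(est) and groups is not None:
        last = est[(est["year"] == y1) & (est["level"] == "admin2")]
        for a, b in (("CPR", "intention_to_use"), ("mCPR", "intention_to_use"),
                     ("CPR", "mCPR"), ("mCPR", "met_need")):
            va = last[last["indicator"] == a].sort_values("unit")["mean"].to_numpy()
            vb = last[last["indicator"] == b].sort_values("unit")["mean"].to_numpy()
            try:
                corr_rows.append({"indicator_a": a, "indicator_b": b,
                                  "level": "admin2", "year": y1,
                                  "rho": correlate(va, vb)})
            except ValueError:
                pass
    results["correlations"] = pd.DataFrame(corr_rows)
    timings["aggregate"] = time.perf_counter() - t0
    return results


def _unit_weight_totals(weights: np.ndarray, geo, level: str) -> np.ndarray:
    ids = _unit_ids(geo, level)
    n_units = int(ids.max()) + 1
    w = weights.mean(axis=0) if weights.ndim == 3 else weights
    out = np.zeros((w.shape[0], n_units))
    for u in range(n_units):
        out[:, u] = w[:, ids == u].sum(axis=1)
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the whole pipeline and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.perf_counter()
    world = generate_world(dataclasses.replace(cfg.world, seed=cfg.seed))
    timings["world"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    micro = simulate_microdata(world, cfg.surveys, seed=cfg.seed + 100)
    timings["surveys"] = time.perf_counter() - t0
    # write inputs immediately so a later stage failure preserves them
    micro.to_csv(out / "microdata.csv", index=False, float_format=_FLOAT_FMT)

    results = run_estimation(world, micro, cfg)
    timings.update(results["timings"])

    t0 = time.perf_counter()
    results["observations"].to_csv(out / "observations.csv", index=False,
                                   float_format=_FLOAT_FMT)
    results["estimates"].to_csv(out / "estimates.csv", index=False,
                                float_format=_FLOAT_FMT)
    results["changes"].to_csv(out / "changes.csv", index=False,
                              float_format=_FLOAT_FMT)
    results["correlations"].to_csv(out / "correlations.csv", index=False,
                                   float_format=_FLOAT_FMT)
    with open(out / "crosswalk_models.json", "w") as f:
        json.dump({f"{r}:{i}": dataclasses.asdict(m)
                   for (r, i), m in results["crosswalk_models"].items()}, f, indent=2)

    surf = {}
    for name, vals in results["indicator_draws"].items():
        surf[f"{name}_mean"] = vals.mean(axis=0)
        surf[f"{name}_lower"] = draw_quantile(vals, 2.5, axis=0)
        surf[f"{name}_upper"] = draw_quantile(vals, 97.5, axis=0)
    np.savez_compressed(out / "surfaces.npz", years=np.array(world.years), **surf)
    timings["write"] = time.perf_counter() - t0

    manifest = {
        "fpgrid_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "n_draws": cfg.n_draws,
        "indicators": list(cfg.indicators),
        "config": config_dict(cfg),
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "hyperparameters": {
            name: {"range_km": f.range_km, "spatial_sd": f.spatial_sd,
                   "ar1": f.ar1, "nugget_sd": f.nugget_sd,
                   "static_sd": f.static_sd,
                   "weights": f.weights.tolist(), "intercept": f.intercept}
            for name, f in results["fits"].items()},
        "outputs": ["microdata.csv", "observations.csv", "estimates.csv",
                    "changes.csv", "correlations.csv", "crosswalk_models.json",
                    "surfaces.npz"],
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return out


def config_dict(cfg: PipelineConfig) -> dict:
    d = {
        "world": config_to_dict(cfg.world),
        "surveys": [dataclasses.asdict(s) for s in cfg.surveys],
        "indicators": list(cfg.indicators),
        "n_draws": cfg.n_draws,
        "max_resample_points": cfg.max_resample_points,
        "skip_crosswalk": cfg.skip_crosswalk,
        "stacker": dataclasses.asdict(cfg.stacker),
        "priors": dataclasses.asdict(cfg.priors),
        "seed": cfg.seed,
    }
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    wd = dict(d.get("world", {}))
    fp = wd.pop("field_params", None)
    if fp is not None:
        from .world import FieldParams
        wd["field_params"] = {k: FieldParams(**{kk: tuple(vv) if kk == "betas" else vv
                                                for kk, vv in v.items()})
                              for k, v in fp.items()}
    if "years" in wd:
        wd["years"] = tuple(wd["years"])
    world = WorldConfig(**wd)
    surveys = [SurveyDesignSpec(**s) for s in d.get("surveys", [])]
    return PipelineConfig(
        world=world, surveys=surveys,
        indicators=tuple(d.get("indicators", NESTED_INDICATORS)),
        n_draws=int(d.get("n_draws", 1000)),
        max_resample_points=int(d.get("max_resample_points", 100)),
        skip_crosswalk=bool(d.get("skip_crosswalk", False)),
        stacker=StackerConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in d.get("stacker", {}).items()}),
        priors=GeostatPriors(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d.get("priors", {}).items()}),
        seed=int(d.get("seed", 0)))


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f) or {})
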