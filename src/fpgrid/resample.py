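"""Population-proportional resampling of polygon-referenced observations.

The stage-2 geostatistical model consumes point data only.  Observations
geo-located to an admin polygon are replaced by pseudo-points at grid-cell
centers inside the polygon, selected by population-weighted sampling without
replacement, each inheriting the parent prevalence and a population-
proportional share of the parent's effective sample size.  The total
effective sample size is conserved exactly per parent observation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .world import GeographySpec


def resample_polygon(obs: pd.Series, geo: GeographySpec, pop_year: np.ndarray,
                     rng: np.random.Generator, max_points: int = 100) -> pd.DataFrame:
    """Resample one polygon observation into pseudo-point observations.

    ``obs`` must carry ``polygon_level`` ("admin1" or "admin2"),
    ``polygon_id``, ``prevalence`` and ``n_eff``.  ``pop_year`` is the
    population raster for the observation year.  Up to ``max_points`` cells
    are drawn without replacement with probability proportional to
    population (all cells if the polygon has fewer); ``n_eff`` is split
    proportional to the selected cells' population and renormalised so the
    shares sum to the parent ``n_eff`` exactly.
    """
    level = obs["polygon_level"]
    pid = int(obs["polygon_id"])
    if level == "admin1":
        cells = geo.cells_in_admin1(pid)
    elif level == "admin2":
        cells = geo.cells_in_admin2(pid)
    else:
        raise ValueError(f"observation is not polygon-located (level={level!r})")
    if len(cells) == 0:
        raise ValueError(f"polygon {level}:{pid} resolves to no cells")
    w = np.asarray(pop_year, float)[cells]
    total = w.sum()
    if total <= 0:
        raise ValueError(f"polygon {level}:{pid} has zero population")

    k = min(int(max_points), len(cells))
    if k == len(cells):
        chosen = cells
        wsel = w
    else:
        idx = rng.choice(len(cells), size=k, replace=False, p=w / total)
        chosen = cells[idx]
        wsel = w[idx]

    shares = wsel / wsel.sum() * float(obs["n_eff"])
    xy = geo.cell_centers()[chosen]
    out = pd.DataFrame({
        "survey_id": obs["survey_id"],
        "indicator": obs["indicator"],
        "year": int(obs["year"]),
        "x_km": xy[:, 0],
        "y_km": xy[:, 1],
        "polygon_level": "",
        "polygon_id": -1,
        "prevalence": float(obs["prevalence"]),
        "n_eff": shares,
        "n_raw": np.nan,
        "tags": obs.get("tags", ""),
        "parent_id": obs.get("obs_id", f"{obs['survey_id']}:{level}:{pid}"),
        "point_weight": wsel,
    })
    # exact conservation despite floating-point renormalisation
    out.loc[out.index[-1], "n_eff"] += float(obs["n_eff"]) - out["n_eff"].sum()
    return out


def resample_observations(obs: pd.DataFrame, geo: GeographySpec,
                          population: np.ndarray, years: tuple[int, ...],
                          seed: int, max_points: int = 100) -> pd.DataFrame:
    """Resample every polygon observation in a table; pass points through.

    ``population`` is the (n_years, n_cells) raster aligned to ``years``.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    is_poly = obs["polygon_level"].fillna("").ne("")
    points = obs.loc[~is_poly].copy()
    points["parent_id"] = ""
    points["point_weight"] = np.nan
    pieces = [points]
    for _, row in obs.loc[is_poly].iterrows():
        t = list(years).index(int(row["year"]))
        pieces.append(resample_polygon(row, geo, population[t], rng,
                                       max_points=max_points))
    return pd.concat(pieces, ignore_index=True)
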