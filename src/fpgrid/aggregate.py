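"""Population-weighted aggregation of cell-level draws to admin estimates,
change over time, significance calls and indicator correlations.

Each indicator is aggregated with the population matching its denominator:
the all-women indicators (CPR, mCPR, tCPR, unmet need) use the raster of
women 15-49; met need uses the in-need population ``pop * (1 - A)``; and
intention to use uses the in-need non-using population
``pop * (1 - p_any) * p_need``.  Draw-dependent weights are applied per
draw, before any summarisation.  Point estimates are draw means; 95%
uncertainty intervals are the empirical 2.5th / 97.5th draw percentiles
(median-unbiased quantile estimator, Hyndman-Fan type 8 — at small draw
counts the default linear rule is an inward-biased extreme order statistic).
A change between two years is called statistically
significant when the posterior probability that the difference exceeds zero
is below 2.5% or above 97.5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .world import GeographySpec

ALL_WOMEN_INDICATORS = ("CPR", "mCPR", "tCPR", "unmet_need")


def draw_quantile(a, q, axis=None):
    """Empirical draw quantile (percent scale), median-unbiased estimator."""
    return np.percentile(a, q, axis=axis, method="median_unbiased")


def denominator_weights(indicator: str, pop: np.ndarray,
                        nested: dict[str, np.ndarray] | None = None,
                        groups=None) -> np.ndarray:
    """Per-cell aggregation weights for one indicator.

    ``pop`` is (n_years, n_cells).  For met need and intention to use the
    weights depend on the nested draws and are returned per draw with shape
    (n_draws, n_years, n_cells); otherwise the population raster is returned
    unchanged.
    """
    if indicator in ALL_WOMEN_INDICATORS:
        return pop
    if indicator == "met_need":
        if groups is None:
            raise ValueError("met_need weights require the group shares")
        return pop[None, :, :] * (1.0 - groups.A)
    if indicator == "intention_to_use":
        if nested is None:
            raise ValueError("intention_to_use weights require the nested draws")
        return pop[None, :, :] * (1.0 - nested["any_use"]) * nested["need_among_nonusers"]
    raise ValueError(f"unknown indicator {indicator!r}")


def _unit_ids(geo: GeographySpec, level: str) -> np.ndarray:
    if level == "admin2":
        return geo.admin2_of_cell
    if level == "admin1":
        return geo.admin1_of_cell
    if level == "national":
        return np.zeros(geo.n_cells, dtype=int)
    raise ValueError(f"unknown admin level {level!r}")


def aggregate_draws(values: np.ndarray, weights: np.ndarray,
                    geo: GeographySpec, level: str) -> np.ndarray:
    """Population-weighted unit aggregates per draw.

    ``values`` is (n_draws, n_years, n_cells); ``weights`` is either
    (n_years, n_cells) or (n_draws, n_years, n_cells).  Returns
    (n_draws, n_years, n_units).  Cells with NaN values get zero weight
    (met need where nobody is in need).  Units whose total weight is zero
    yield NaN with a warning.
    """
    ids = _unit_ids(geo, level)
    n_units = int(ids.max()) + 1
    if weights.ndim == 2:
        weights = np.broadcast_to(weights[None, :, :], values.shape)
    w = np.where(np.isnan(values), 0.0, weights)
    v = np.where(np.isnan(values), 0.0, values)
    nd, ny, nc = values.shape
    num = np.zeros((nd, ny, n_units))
    den = np.zeros((nd, ny, n_units))
    for u in range(n_units):
        m = ids == u
        num[:, :, u] = (v[:, :, m] * w[:, :, m]).sum(axis=2)
        den[:, :, u] = w[:, :, m].sum(axis=2)
    if np.any(den == 0):
        warnings.warn("unit-year(s) with zero total weight; estimate set to NaN",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def summarize_estimates(unit_draws: np.ndarray, indicator: str, level: str,
                        years: tuple[int, ...],
                        denom: np.ndarray | None = None) -> pd.DataFrame:
    """Draw means and 2.5/97.5 percentile bounds as an estimates table."""
    nd, ny, nu = unit_draws.shape
    mean = unit_draws.mean(axis=0)
    lower = draw_quantile(unit_draws, 2.5, axis=0)
    upper = draw_quantile(unit_draws, 97.5, axis=0)
    rows = []
    for t, year in enumerate(years):
        for u in range(nu):
            rows.append({
                "indicator": indicator, "level": level, "unit": u,
                "year": year, "mean": mean[t, u],
                "lower": lower[t, u], "upper": upper[t, u],
                "denominator": float(denom[t, u]) if denom is not None else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class ChangeEstimate:
    indicator: str
    level: str
    unit: int
    year_start: int
    year_end: int
    change_ppt: float
    lower_ppt: float
    upper_ppt: float
    prob_increase: float
    significant: bool


def change_over_time(unit_draws: np.ndarray, years: tuple[int, ...],
                     indicator: str, level: str, y0: int, y1: int) -> list[ChangeEstimate]:
    """Per-unit change between two years, in percentage points, with the
    2.5%/97.5% posterior-probability significance rule."""
    if y0 not in years or y1 not in years:
        raise ValueError("both years must be within the estimated range")
    if y0 == y1:
        warnings.warn("start and end year identical; change is zero", stacklevel=2)
    t0, t1 = years.index(y0), years.index(y1)
    diff = (unit_draws[:, t1, :] - unit_draws[:, t0, :]) * 100.0  # (n_draws, n_units)
    out = []
    for u in range(diff.shape[1]):
        d = diff[:, u]
        prob = float((d > 0).mean())
        out.append(ChangeEstimate(
            indicator, level, u, y0, y1,
            float(d.mean()),
            float(draw_quantile(d, 2.5)), float(draw_quantile(d, 97.5)),
            prob, bool(prob < 0.025 or prob > 0.975)))
    return out


def changes_frame(changes: list[ChangeEstimate]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in changes])


def correlate(est_a: np.ndarray, est_b: np.ndarray) -> float:
    """Pearson correlation of two indicators' unit-level point estimates."""
    a = np.asarray(est_a, float)
    b = np.asarray(est_b, float)
    if len(a) < 3:
        raise ValueError("need at least 3 units to correlate")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in point estimates")
    return float(stats.pearsonr(a, b)[0])
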