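"""Crosswalking of observations from surveys with restricted designs.

Three questionnaire restrictions limit comparability across surveys:

* ``ever_married_only`` — sexual-activity and contraception questions asked
  only of ever-married women (affects all four nested indicators);
* ``missing_need_components`` — wantedness/fecundity items absent, so need is
  derived with a partial definition (affects need and intent);
* ``intent_12m_horizon`` — intention asked for the next 12 months only
  (affects intent).

Surveys with no intention question at all are never crosswalked; they are
simply excluded from intent modelling.

For each restriction type, a crosswalk model is the weighted mean logit
difference (full-definition minus restricted-definition prevalence) over
reference surveys where both definitions are computable, with its residual
variance.  Applying a model shifts an observation's prevalence on the logit
scale and deflates its effective sample size so that the implied binomial
variance plus the crosswalk residual variance (delta method, logit scale)
equals the adjusted observation's total variance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

RESTRICTION_TYPES = ("ever_married_only", "missing_need_components",
                     "intent_12m_horizon")

#: indicators each restriction affects (and hence is crosswalked for)
AFFECTED_INDICATORS = {
    "ever_married_only": ("any_use", "modern_among_users", "need_among_nonusers",
                          "intent_among_inneed_nonusers"),
    "missing_need_components": ("need_among_nonusers",
                                "intent_among_inneed_nonusers"),
    "intent_12m_horizon": ("intent_among_inneed_nonusers",),
}

_EPS = 1e-6


@dataclass
class CrosswalkModel:
    restriction: str
    coefficient: float        # mean logit(full) - logit(restricted)
    residual_variance: float  # between-pair variance not explained by the shift
    coefficient_se: float
    n_pairs: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CrosswalkModel":
        return cls(**json.loads(s))


def _continuity_correct(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    lo = 1.0 / (2.0 * np.maximum(n, 1.0))
    out = np.clip(p, lo, 1.0 - lo)
    if np.any(out != p):
        warnings.warn("prevalence at 0 or 1: continuity correction applied",
                      stacklevel=3)
    return out


def fit_crosswalk(pairs: pd.DataFrame, restriction: str) -> CrosswalkModel:
    """Fit a crosswalk model from matched (restricted, full) prevalence pairs.

    ``pairs`` needs columns ``restricted_prev``, ``full_prev`` and optionally
    ``n_eff`` (weights for the weighted least squares).  At least two pairs
    are required; prevalences of exactly 0 or 1 are continuity-corrected with
    a warning.
    """
    if restriction not in RESTRICTION_TYPES:
        raise ValueError(f"unknown restriction type {restriction!r}")
    if len(pairs) < 2:
        raise ValueError("need at least 2 reference pairs to fit a crosswalk")
    w = pairs["n_eff"].to_numpy(float) if "n_eff" in pairs else np.ones(len(pairs))
    n_for_cc = w if "n_eff" in pairs else np.full(len(pairs), 1e6)
    pr = _continuity_correct(pairs["restricted_prev"].to_numpy(float), n_for_cc)
    pf = _continuity_correct(pairs["full_prev"].to_numpy(float), n_for_cc)
    d = logit(pf) - logit(pr)
    wsum = w.sum()
    coef = float((w * d).sum() / wsum)
    resid = d - coef
    # weighted unbiased variance of the pair-level differences
    denom = wsum - (w ** 2).sum() / wsum
    var = float((w * resid ** 2).sum() / denom) if denom > 0 else 0.0
    var = max(var, 0.0)
    se = float(np.sqrt(var / len(d))) if len(d) > 1 else np.inf
    return CrosswalkModel(restriction, coef, var, se, int(len(pairs)))


def _logit_var(p: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    return 1.0 / (n_eff * p * (1.0 - p))


def apply_crosswalk(model: CrosswalkModel, obs: pd.DataFrame) -> pd.DataFrame:
    """Adjust restricted observations to the reference definition.

    Every row of ``obs`` must carry the model's restriction tag.  The
    adjusted prevalence is ``expit(logit(p) + coefficient)``; ``n_eff`` is
    deflated so the total logit-scale variance equals the binomial variance
    plus the crosswalk residual variance.  Output rows gain a
    ``crosswalked:<restriction>`` provenance tag.
    """
    if len(obs) == 0:
        return obs.copy()
    tags = obs["tags"].fillna("")
    if not tags.str.contains(model.restriction).all():
        raise ValueError(
            f"observations lack the {model.restriction!r} restriction tag")
    out = obs.copy()
    n = out["n_eff"].to_numpy(float)
    p = _continuity_correct(out["prevalence"].to_numpy(float), n)
    p_adj = np.clip(expit(logit(p) + model.coefficient), _EPS, 1.0 - _EPS)
    total_var = _logit_var(p, n) + model.residual_variance
    n_adj = 1.0 / (total_var * p_adj * (1.0 - p_adj))
    # correcting a definition never adds information
    n_adj = np.minimum(n_adj, n)
    out["prevalence"] = p_adj
    out["n_eff"] = n_adj
    out["tags"] = tags + "|crosswalked:" + model.restriction
    return out


def build_reference_pairs(micro_by_survey: dict[str, pd.DataFrame],
                          restriction: str, indicator: str) -> pd.DataFrame:
    """Compute survey-level (restricted, full) prevalence pairs for one
    restriction type and indicator, from unrestricted reference microdata.

    Both definitions are computed on the same respondents: the ever-married
    restriction subsets to ever-married women; the missing-need restriction
    re-derives need with the partial definition; the horizon restriction
    reads the 12-month intent item.
    """
    from .indicators import derive_flags_frame

    rows = []
    for sid, micro in micro_by_survey.items():
        tags = micro["tags"].fillna("") if "tags" in micro else pd.Series("", index=micro.index)
        if tags.str.contains("|".join(RESTRICTION_TYPES) + "|no_intent_question").any():
            continue  # not a reference survey
        full = derive_flags_frame(micro)
        if restriction == "ever_married_only":
            restricted = full[full["ever_married"]]
        elif restriction == "missing_need_components":
            forced = micro.copy()
            forced["tags"] = "missing_need_components"
            restricted = derive_flags_frame(forced)
        elif restriction == "intent_12m_horizon":
            forced = micro.copy()
            forced["tags"] = "intent_12m_horizon"
            restricted = derive_flags_frame(forced)
        else:
            raise ValueError(f"unknown restriction type {restriction!r}")
        col = f"flag_{indicator}"
        f_sub = full[full[col].notna()]
        r_sub = restricted[restricted[col].notna()]
        if len(f_sub) < 10 or len(r_sub) < 10:
            continue
        wf, wr = f_sub["weight"].to_numpy(), r_sub["weight"].to_numpy()
        rows.append({
            "survey_id": sid,
            "full_prev": float((wf * f_sub[col]).sum() / wf.sum()),
            "restricted_prev": float((wr * r_sub[col]).sum() / wr.sum()),
            "n_eff": float(wr.sum() ** 2 / (wr ** 2).sum()),
        })
    return pd.DataFrame(rows)


def fit_crosswalk_models(micro_by_survey: dict[str, pd.DataFrame],
                         restrictions_present: set[str],
                         ) -> dict[tuple[str, str], CrosswalkModel]:
    """Fit one crosswalk per (restriction, affected indicator) pair, from the
    unrestricted reference surveys.  The coefficient is a single constant per
    pair (no covariate dependence)."""
    models: dict[tuple[str, str], CrosswalkModel] = {}
    for restriction in RESTRICTION_TYPES:
        if restriction not in restrictions_present:
            continue
        for indicator in AFFECTED_INDICATORS[restriction]:
            pairs = build_reference_pairs(micro_by_survey, restriction, indicator)
            if len(pairs) < 2:
                warnings.warn(
                    f"fewer than 2 reference pairs for {restriction}/{indicator}; "
                    "restricted observations left unadjusted", stacklevel=2)
                continue
            models[(restriction, indicator)] = fit_crosswalk(pairs, restriction)
    return models


def crosswalk_observations(obs: pd.DataFrame,
                           models: dict[tuple[str, str], CrosswalkModel],
                           ) -> pd.DataFrame:
    """Apply the relevant fitted crosswalks to a mixed observation table.

    Observations from surveys without an intent question never contribute
    intent rows (they are dropped upstream); all other restricted rows are
    adjusted for each restriction affecting their indicator, in the fixed
    order of :data:`RESTRICTION_TYPES`.
    """
    out = obs.copy()
    for restriction in RESTRICTION_TYPES:
        for indicator in AFFECTED_INDICATORS[restriction]:
            model = models.get((restriction, indicator))
            if model is None:
                continue
            tags = out["tags"].fillna("")
            mask = (tags.str.contains(restriction)
                    & ~tags.str.contains("crosswalked:" + restriction)
                    & (out["indicator"] == indicator))
            if mask.any():
                out.loc[mask] = apply_crosswalk(model, out.loc[mask])
    return out
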