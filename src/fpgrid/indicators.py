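"""Respondent-level indicator derivation and cluster-level collapse.

Turns questionnaire responses into the four nested indicator outcomes —

* ``any_use``: currently using any method of contraception;
* ``modern_among_users``: using at least one modern method, among users;
* ``need_among_nonusers``: in need of family planning, among non-users;
* ``intent_among_inneed_nonusers``: intending future use, among in-need
  non-users —

then collapses microdata to one observation per cluster (or polygon) with the
survey-weighted prevalence and the Kish effective sample size.

Method classification and the need-for-family-planning decision tree follow
the GBD-style definitions: a current user of any method is in need; a
pregnant (or postpartum-amenorrheic within 24 months) woman is in need iff
the (last) pregnancy was unwanted or wanted later; otherwise women who are
not sexually active or infecund are not in need, and the remaining women are
in need unless they want a(nother) child within two years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

NESTED_INDICATORS = ("any_use", "modern_among_users", "need_among_nonusers",
                     "intent_among_inneed_nonusers")

#: modern methods; everything else in the vocabulary is traditional
MODERN_METHODS = frozenset({
    "pills", "condoms", "diaphragm", "spermicide_sponge", "implant",
    "injection", "iud", "male_sterilization", "female_sterilization",
    "patch", "ring", "emergency",
})

TRADITIONAL_METHODS = frozenset({
    "rhythm", "sdm_beads", "lam", "withdrawal", "herbal", "charms_amulets",
    "other_traditional",
})

METHOD_VOCABULARY = MODERN_METHODS | TRADITIONAL_METHODS


class NeedStatus(Enum):
    IN_NEED = "in_need"
    NOT_IN_NEED = "not_in_need"
    INDETERMINABLE = "indeterminable"


def classify_method(method_code: str) -> str:
    """Classify a contraceptive method code as ``"modern"`` or ``"traditional"``.

    Unknown codes are rejected (never silently treated as traditional).
    """
    if method_code in MODERN_METHODS:
        return "modern"
    if method_code in TRADITIONAL_METHODS:
        return "traditional"
    raise ValueError(f"unknown contraceptive method code: {method_code!r}")


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    if isinstance(v, str) and v == "":
        return True
    return False


def _infecund(rec) -> bool:
    markers = (rec.get("cannot_have_children"), rec.get("menopausal"),
               rec.get("hysterectomy"), rec.get("never_menstruated"))
    if any(_is_missing(m) for m in markers):
        raise KeyError("infecundity markers missing")
    if any(bool(m) for m in markers):
        return True
    ym = rec.get("years_married")
    eu = rec.get("ever_used_contraception")
    gb = rec.get("ever_gave_birth")
    if _is_missing(ym) or _is_missing(eu) or _is_missing(gb):
        raise KeyError("infecundity rule fields missing")
    if float(ym) >= 5.0 and not bool(eu) and not bool(gb):
        return True
    if bool(gb):
        ylb = rec.get("years_since_last_birth")
        psb = rec.get("period_since_last_birth")
        if _is_missing(ylb) or _is_missing(psb):
            raise KeyError("last-birth fields missing")
        if float(ylb) >= 5.0 and not bool(psb):
            return True
    return False


def determine_need(record) -> NeedStatus:
    """Need-for-family-planning decision tree for one respondent.

    ``record`` is any mapping (dict, Series).  Evaluation order: current use
    first, then the pregnancy/postpartum branches on wantedness, then the
    sexual-activity and infecundity screens, then fertility preference.
    Missing fields on the branch actually taken yield
    ``NeedStatus.INDETERMINABLE`` (consumed by the crosswalk stage).
    """
    method = record.get("current_method")
    if not _is_missing(method):
        classify_method(method)  # vocabulary guard
        return NeedStatus.IN_NEED

    status = record.get("pregnancy_status")
    if _is_missing(status):
        return NeedStatus.INDETERMINABLE
    if status in ("pregnant", "postpartum_amenorrheic"):
        want = record.get("wantedness")
        if _is_missing(want) or want == "unknown":
            return NeedStatus.INDETERMINABLE
        if want in ("later", "unwanted"):
            return NeedStatus.IN_NEED
        if want == "then":
            return NeedStatus.NOT_IN_NEED
        raise ValueError(f"unknown wantedness category: {want!r}")
    if status != "neither":
        raise ValueError(f"unknown pregnancy status: {status!r}")

    sa = record.get("sexually_active")
    if _is_missing(sa):
        return NeedStatus.INDETERMINABLE
    if not bool(sa):
        return NeedStatus.NOT_IN_NEED
    try:
        if _infecund(record):
            return NeedStatus.NOT_IN_NEED
    except KeyError:
        return NeedStatus.INDETERMINABLE

    pref = record.get("fertility_pref")
    if _is_missing(pref):
        return NeedStatus.INDETERMINABLE
    if pref in ("wants_none", "undecided", "wants_after_2y"):
        return NeedStatus.IN_NEED
    if pref == "wants_within_2y":
        return NeedStatus.NOT_IN_NEED
    raise ValueError(f"unknown fertility preference: {pref!r}")


def determine_need_partial(record) -> NeedStatus:
    """Fallback need definition for surveys missing the wantedness and
    fecundity items: current use, then sexual activity, then fertility
    preference only.  Systematically different from :func:`determine_need`;
    observations derived with it carry the ``missing_need_components`` tag and
    are crosswalked to the reference definition downstream.
    """
    method = record.get("current_method")
    if not _is_missing(method):
        return NeedStatus.IN_NEED
    sa = record.get("sexually_active")
    if _is_missing(sa):
        return NeedStatus.INDETERMINABLE
    if not bool(sa):
        return NeedStatus.NOT_IN_NEED
    pref = record.get("fertility_pref")
    if _is_missing(pref):
        return NeedStatus.INDETERMINABLE
    if pref == "wants_within_2y":
        return NeedStatus.NOT_IN_NEED
    if pref in ("wants_none", "undecided", "wants_after_2y"):
        return NeedStatus.IN_NEED
    raise ValueError(f"unknown fertility preference: {pref!r}")


@dataclass
class NestedFlags:
    """Nested indicator outcomes for one respondent; ``None`` = not applicable
    or indeterminable."""

    any_use: int
    modern_among_users: int | None
    need_among_nonusers: int | None
    intent_among_inneed_nonusers: int | None


def derive_nested_flags(record, partial_need: bool = False,
                        intent_item: str = "intent_any") -> NestedFlags:
    """Derive the four nested flags for one respondent record."""
    method = record.get("current_method")
    using = not _is_missing(method)
    if using:
        modern = 1 if classify_method(method) == "modern" else 0
        return NestedFlags(1, modern, None, None)

    need_fn = determine_need_partial if partial_need else determine_need
    status = need_fn(record)
    if status is NeedStatus.INDETERMINABLE:
        return NestedFlags(0, None, None, None)
    if status is NeedStatus.NOT_IN_NEED:
        return NestedFlags(0, None, 0, None)

    ans = record.get(intent_item)
    if _is_missing(ans):
        intent = None
    else:
        # "unsure" responses count as not intending
        intent = 1 if ans == "yes" else 0
    return NestedFlags(0, None, 1, intent)


def derive_flags_frame(micro: pd.DataFrame) -> pd.DataFrame:
    """Vectorised flag derivation for a microdata table.

    Surveys tagged ``missing_need_components`` are derived with the partial
    need definition; surveys tagged ``intent_12m_horizon`` read the 12-month
    intent item.  Returns the input with four added float columns (NaN = not
    applicable / indeterminable).
    """
    df = micro.copy()
    tags = df.get("tags", pd.Series("", index=df.index)).fillna("")
    partial = tags.str.contains("missing_need_components")
    horizon = tags.str.contains("intent_12m_horizon")
    no_intent = tags.str.contains("no_intent_question")

    method = df["current_method"].fillna("")
    using = method != ""
    unknown = using & ~method.isin(METHOD_VOCABULARY)
    if unknown.any():
        raise ValueError(
            f"unknown contraceptive method code(s): {sorted(method[unknown].unique())}")
    modern = method.isin(MODERN_METHODS)

    flags = pd.DataFrame(index=df.index, dtype=float)
    flags["any_use"] = using.astype(float)
    flags["modern_among_users"] = np.where(using, modern.astype(float), np.nan)

    need = np.full(len(df), np.nan)
    nonusers = ~using
    rows = df.loc[nonusers]
    need_vals = []
    for (is_partial,), sub in rows.groupby([partial[nonusers]], sort=False):
        fn = determine_need_partial if is_partial else determine_need
        vals = sub.apply(lambda r: fn(r), axis=1)
        need_vals.append(vals)
    if need_vals:
        all_vals = pd.concat(need_vals).reindex(rows.index)
        need[nonusers.to_numpy()] = [
            1.0 if v is NeedStatus.IN_NEED else
            0.0 if v is NeedStatus.NOT_IN_NEED else np.nan
            for v in all_vals]
    flags["need_among_nonusers"] = need

    intent_col = np.where(horizon, df.get("intent_12m", ""), df.get("intent_any", ""))
    intent_col = pd.Series(intent_col, index=df.index).fillna("")
    applicable = nonusers & (need == 1.0) & ~no_intent & (intent_col != "")
    flags["intent_among_inneed_nonusers"] = np.where(
        applicable, (intent_col == "yes").astype(float), np.nan)

    for c in flags.columns:
        df[f"flag_{c}"] = flags[c]
    return df


def kish_neff(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2`` of a weight vector."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return float(w.sum() ** 2 / (w ** 2).sum())


def collapse_clusters(micro: pd.DataFrame, indicator: str) -> pd.DataFrame:
    """Collapse flagged microdata to cluster-level observations for one
    nested indicator.

    Point-located surveys collapse per cluster; polygon-located surveys
    collapse per polygon.  Prevalence is the weighted mean of the indicator
    flag over applicable respondents; ``n_eff`` is the Kish effective sample
    size of the same weights.  Clusters with no applicable respondents emit
    nothing.

    Returns the standard observation table with columns (survey_id,
    indicator, year, x_km, y_km, polygon_level, polygon_id, prevalence,
    n_eff, n_raw, tags).
    """
    if indicator not in NESTED_INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    col = f"flag_{indicator}"
    if col not in micro.columns:
        micro = derive_flags_frame(micro)
    usable = micro[micro[col].notna()]
    if len(usable) == 0:
        warnings.warn(f"no applicable respondents for {indicator}; empty output",
                      stacklevel=2)
        return _empty_obs_frame()

    is_polygon = usable["polygon_level"].fillna("").ne("") if "polygon_level" in usable \
        else pd.Series(False, index=usable.index)
    keys = ["survey_id", "year"]
    group_col = np.where(is_polygon, usable.get("polygon_id", -1), usable["cluster_id"])
    usable = usable.assign(_group=group_col)

    rows = []
    for (sid, year, g), sub in usable.groupby(keys + ["_group"], sort=True):
        w = sub["weight"].to_numpy(float)
        y = sub[col].to_numpy(float)
        poly = sub["polygon_level"].iloc[0] if "polygon_level" in sub else ""
        if poly is None or poly != poly:   # NaN from CSV round-trips
            poly = ""
        tags = sub["tags"].iloc[0] if "tags" in sub else ""
        if tags is None or tags != tags:
            tags = ""
        rows.append({
            "survey_id": sid, "indicator": indicator, "year": int(year),
            "x_km": float(sub["x_km"].mean()) if poly == "" else np.nan,
            "y_km": float(sub["y_km"].mean()) if poly == "" else np.nan,
            "polygon_level": poly,
            "polygon_id": int(g) if poly else -1,
            "prevalence": float((w * y).sum() / w.sum()),
            "n_eff": kish_neff(w),
            "n_raw": int(len(sub)),
            "tags": tags,
        })
    return pd.DataFrame(rows)


def _empty_obs_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "survey_id", "indicator", "year", "x_km", "y_km", "polygon_level",
        "polygon_id", "prevalence", "n_eff", "n_raw", "tags"])
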