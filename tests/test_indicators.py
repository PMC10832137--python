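"""Indicator derivation: method classification, the need decision tree
(checked against an exhaustive flat-logic oracle), nested flags, Kish
effective sample size and cluster collapse."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpgrid import (NeedStatus, classify_method, collapse_clusters,
                    derive_flags_frame, derive_nested_flags, determine_need,
                    kish_neff)
from fpgrid.indicators import MODERN_METHODS, TRADITIONAL_METHODS

from conftest import make_record


class TestClassifyMethod:
    @pytest.mark.parametrize("code,expected", [
        ("injection", "modern"), ("pills", "modern"), ("iud", "modern"),
        ("emergency", "modern"), ("patch", "modern"),
        ("withdrawal", "traditional"), ("lam", "traditional"),
        ("rhythm", "traditional"), ("charms_amulets", "traditional"),
    ])
    def test_known_codes(self, code, expected):
        assert classify_method(code) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            classify_method("unknown_999")

    def test_vocabulary_is_partitioned(self):
        assert not (MODERN_METHODS & TRADITIONAL_METHODS)


class TestDetermineNeed:
    def test_pregnant_wanted_later_in_need(self):
        rec = make_record(pregnancy_status="pregnant", wantedness="later")
        assert determine_need(rec) is NeedStatus.IN_NEED

    def test_infecundity_rule_married_never_used_never_birth(self):
        rec = make_record(years_married=6.0, ever_used_contraception=False,
                          ever_gave_birth=False, fertility_pref="wants_none")
        assert determine_need(rec) is NeedStatus.NOT_IN_NEED

    def test_current_use_overrides_everything(self):
        rec = make_record(current_method="pills",
                          fertility_pref="wants_within_2y")
        assert determine_need(rec) is NeedStatus.IN_NEED

    def test_missing_wantedness_indeterminable(self):
        rec = make_record(pregnancy_status="pregnant", wantedness="")
        assert determine_need(rec) is NeedStatus.INDETERMINABLE


def _oracle_need(rec):
    """Flat set-logic re-statement of the need definition (no sequential
    tree): each status is characterised independently."""
    using = rec["current_method"] != ""
    if using:
        return NeedStatus.IN_NEED
    status = rec["pregnancy_status"]
    if status in ("pregnant", "postpartum_amenorrheic"):
        w = rec["wantedness"]
        if w in ("later", "unwanted"):
            return NeedStatus.IN_NEED
        if w == "then":
            return NeedStatus.NOT_IN_NEED
        return NeedStatus.INDETERMINABLE
    sa = rec["sexually_active"]
    if sa is None:
        return NeedStatus.INDETERMINABLE
    if sa is False:
        return NeedStatus.NOT_IN_NEED
    # fecundity: three-valued
    marker = rec["menopausal"]
    if marker is None:
        fecund = None
    elif marker:
        fecund = False
    elif rec["years_married"] >= 5 and not rec["ever_used_contraception"] \
            and not rec["ever_gave_birth"]:
        fecund = False
    elif rec["ever_gave_birth"] and rec["years_since_last_birth"] >= 5 \
            and not rec["period_since_last_birth"]:
        fecund = False
    else:
        fecund = True
    if fecund is None:
        return NeedStatus.INDETERMINABLE
    if fecund is False:
        return NeedStatus.NOT_IN_NEED
    pref = rec["fertility_pref"]
    if pref == "":
        return NeedStatus.INDETERMINABLE
    if pref == "wants_within_2y":
        return NeedStatus.NOT_IN_NEED
    return NeedStatus.IN_NEED


def test_need_matches_exhaustive_oracle():
    """determine_need agrees with the flat-logic oracle on the full cross
    product of decision-tree inputs."""
    grid = itertools.product(
        ["", "pills"],                                     # current_method
        ["pregnant", "postpartum_amenorrheic", "neither"],  # pregnancy status
        ["then", "later", "unwanted", ""],                  # wantedness
        [True, False, None],                                # sexually_active
        [True, False, None],                                # menopausal marker
        [2.0, 6.0],                                         # years_married
        [True, False],                                      # ever_used
        [True, False],                                      # ever_gave_birth
        [1.0, 6.0],                                         # years since birth
        [True, False],                                      # period since birth
        ["wants_within_2y", "wants_after_2y", "wants_none", "undecided", ""],
    )
    n = 0
    for (cm, ps, wa, sa, meno, ym, eu, gb, ylb, psb, pref) in grid:
        rec = make_record(
            current_method=cm, pregnancy_status=ps, wantedness=wa,
            sexually_active=sa, menopausal=meno, years_married=ym,
            ever_used_contraception=eu, ever_gave_birth=gb,
            years_since_last_birth=ylb, period_since_last_birth=psb,
            fertility_pref=pref)
        if meno is None:
            rec["menopausal"] = np.nan
        if sa is None:
            rec["sexually_active"] = np.nan
        assert determine_need(rec) is _oracle_need(
            {**rec, "menopausal": meno, "sexually_active": sa}), rec
        n += 1
    assert n == 2 * 3 * 4 * 3 * 3 * 2 * 2 * 2 * 2 * 2 * 5


class TestNestedFlags:
    def test_modern_user_structure(self):
        f = derive_nested_flags(make_record(current_method="implant"))
        assert (f.any_use, f.modern_among_users) == (1, 1)
        assert f.need_among_nonusers is None
        assert f.intent_among_inneed_nonusers is None

    def test_traditional_only_user(self):
        f = derive_nested_flags(make_record(current_method="withdrawal"))
        assert (f.any_use, f.modern_among_users) == (1, 0)

    def test_inneed_nonuser_with_intent(self):
        rec = make_record(fertility_pref="wants_none", intent_any="yes")
        f = derive_nested_flags(rec)
        assert (f.any_use, f.need_among_nonusers,
                f.intent_among_inneed_nonusers) == (0, 1, 1)
        assert f.modern_among_users is None

    def test_flag_applicability_partition(self, small_micro):
        """any_use applicable everywhere; modern + need applicabilities
        partition the records."""
        df = derive_flags_frame(small_micro)
        n = len(df)
        assert df["flag_any_use"].notna().sum() == n
        assert (df["flag_modern_among_users"].notna().sum()
                + df["flag_need_among_nonusers"].notna().sum()) == n


class TestKishNeff:
    @pytest.mark.parametrize("weights,expected", [
        ([1, 1, 1, 1], 4.0),
        ([1, 1, 2], 16 / 6),
        ([5], 1.0),
    ])
    def test_values(self, weights, expected):
        assert kish_neff(weights) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [[], [0.0, 1.0], [-1.0, 2.0], [np.inf]])
    def test_invalid_weights_rejected(self, bad):
        with pytest.raises(ValueError):
            kish_neff(bad)

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1,
                    max_size=50))
    @settings(deadline=None, max_examples=200)
    def test_bounds_property(self, weights):
        neff = kish_neff(weights)
        assert 1.0 - 1e-9 <= neff <= len(weights) + 1e-9
        if len(set(weights)) == 1:
            assert neff == pytest.approx(len(weights))


class TestCollapseClusters:
    def _micro(self, rows):
        base = {"survey_id": "S", "year": 2001, "x_km": 2.5, "y_km": 2.5,
                "polygon_level": "", "polygon_id": -1, "tags": ""}
        return pd.DataFrame([dict(make_record(**r), **base, cluster_id=c)
                             for c, r in rows])

    def test_hand_computed_weighted_prevalence_and_neff(self):
        """Three users, weights [1,1,2], modern flags [1,0,1]: modern-share
        prevalence 0.75 with Kish n_eff 16/6."""
        micro = self._micro([
            (0, {"current_method": "pills", "weight": 1.0}),
            (0, {"current_method": "withdrawal", "weight": 1.0}),
            (0, {"current_method": "iud", "weight": 2.0}),
        ])
        obs = collapse_clusters(micro, "modern_among_users")
        assert len(obs) == 1
        assert obs["prevalence"].iloc[0] == pytest.approx(0.75)
        assert obs["n_eff"].iloc[0] == pytest.approx(16 / 6)

    def test_cluster_without_users_emits_nothing(self):
        micro = self._micro([(0, {"current_method": ""}),
                             (0, {"current_method": ""})])
        with pytest.warns(UserWarning):
            obs = collapse_clusters(micro, "modern_among_users")
        assert len(obs) == 0

    def test_uniform_weights_reproduce_unweighted_proportion(self):
        micro = self._micro([
            (0, {"current_method": "pills"}),
            (0, {"current_method": ""}),
            (0, {"current_method": "condoms"}),
            (0, {"current_method": ""}),
        ])
        obs = collapse_clusters(micro, "any_use")
        assert obs["prevalence"].iloc[0] == pytest.approx(0.5)
        assert obs["n_eff"].iloc[0] == pytest.approx(4.0)

    def test_unknown_indicator_rejected(self, small_micro):
        with pytest.raises(ValueError):
            collapse_clusters(small_micro, "mCPR")
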