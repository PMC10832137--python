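"""Deterministic recombination of the four nested probabilities into the five
mutually exclusive population groups and the six final indicators.

With ``p_any`` (any contraceptive use), ``p_mod`` (modern use among users),
``p_need`` (need among non-users) and ``p_int`` (intention among in-need
non-users), the five groups are

* A — not in need:                        ``(1 - p_any) (1 - p_need)``
* B — in need, not using, no intent:      ``(1 - p_any) p_need (1 - p_int)``
* C — in need, not using, intends:        ``(1 - p_any) p_need p_int``
* D — using traditional methods only:     ``p_any (1 - p_mod)``
* E — using modern methods:               ``p_any p_mod``

which sum to one algebraically.  The six indicators follow as CPR = p_any,
mCPR = E, tCPR = D, unmet need = B + C + D, met need = E / (1 - A) and
intention to use = p_int.  By construction CPR = mCPR + tCPR and
met need = mCPR / (mCPR + unmet need) hold on every draw, cell and year.
Recombination is applied per posterior draw, never to draw means, so that
uncertainty propagates through the nonlinear identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GROUP_NAMES = ("A", "B", "C", "D", "E")
INDICATOR_NAMES = ("CPR", "mCPR", "tCPR", "unmet_need", "met_need",
                   "intention_to_use")


@dataclass
class GroupShares:
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray

    def total(self) -> np.ndarray:
        return self.A + self.B + self.C + self.D + self.E


def compute_groups(p_any: np.ndarray, p_mod: np.ndarray, p_need: np.ndarray,
                   p_int: np.ndarray) -> GroupShares:
    """Elementwise group shares from the nested probabilities (arrays of any
    matching shape; values must lie in [0, 1])."""
    for name, arr in (("p_any", p_any), ("p_mod", p_mod),
                      ("p_need", p_need), ("p_int", p_int)):
        arr = np.asarray(arr)
        if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} outside [0, 1]")
    nu = 1.0 - p_any
    return GroupShares(
        A=nu * (1.0 - p_need),
        B=nu * p_need * (1.0 - p_int),
        C=nu * p_need * p_int,
        D=p_any * (1.0 - p_mod),
        E=p_any * p_mod,
    )


def compute_indicators(groups: GroupShares, p_any: np.ndarray,
                       p_int: np.ndarray) -> dict[str, np.ndarray]:
    """Six final indicators from the group shares.

    ``met_need`` is NaN where the in-need share ``1 - A`` vanishes (its
    denominator is empty there); aggregation weights are zero at such cells,
    so the NaN never propagates into population-weighted estimates.
    """
    unmet = groups.B + groups.C + groups.D
    in_need = 1.0 - groups.A
    with np.errstate(divide="ignore", invalid="ignore"):
        met = np.where(in_need > 0, groups.E / np.where(in_need > 0, in_need, 1.0),
                       np.nan)
    return {
        "CPR": np.asarray(p_any, float),
        "mCPR": groups.E,
        "tCPR": groups.D,
        "unmet_need": unmet,
        "met_need": met,
        "intention_to_use": np.asarray(p_int, float),
    }


def recombine_draws(nested: dict[str, np.ndarray]) -> tuple[GroupShares, dict[str, np.ndarray]]:
    """Groups + indicators from draw arrays keyed by nested-indicator name."""
    p_any = nested["any_use"]
    p_mod = nested["modern_among_users"]
    p_need = nested["need_among_nonusers"]
    p_int = nested["intent_among_inneed_nonusers"]
    groups = compute_groups(p_any, p_mod, p_need, p_int)
    return groups, compute_indicators(groups, p_any, p_int)
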