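"""Synthetic country generator: geography, population, covariates, latent truth,
and cluster-sampled survey microdata.

The generator emulates the inputs a subnational family-planning analysis
consumes: a regular grid of ~5x5-km cells nested in a two-level admin
hierarchy, a raster of women aged 15-49 per cell-year, five smooth covariate
surfaces, and latent true surfaces of the four nested indicator probabilities
(any contraceptive use; modern use among users; need for family planning
among non-users; intention to use among in-need non-users).  Surveys are
simulated with the design features real microdata exhibit: cluster sampling
proportional to population, noisy design weights, GPS displacement,
polygon-only geocoding, and questionnaire restrictions that downstream
crosswalking must adjust for.

Latent fields are logit-linear in the standardised covariates plus a
separable space-time Gaussian process (Matern-3/2 in space, AR(1) across
years).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

NESTED_INDICATORS = ("any_use", "modern_among_users", "need_among_nonusers",
                     "intent_among_inneed_nonusers")

GEOCODING_MODES = ("point", "displaced-point", "polygon-admin1", "polygon-admin2")

COVARIATE_NAMES = ("night_lights", "travel_settlement", "travel_health",
                   "population", "female_education")


def matern32(dist: np.ndarray, rng_km: float) -> np.ndarray:
    """Matern-3/2 correlation at distance ``dist`` for range parameter ``rng_km``.

    rho(h) = (1 + sqrt(3) h / r) exp(-sqrt(3) h / r).
    """
    s = np.sqrt(3.0) * np.asarray(dist, dtype=float) / float(rng_km)
    return (1.0 + s) * np.exp(-s)


# ---------------------------------------------------------------------------
# geography


@dataclass(frozen=True)
class GeographySpec:
    """Regular grid partitioned into contiguous admin1 bands and admin2 blocks."""

    nrows: int
    ncols: int
    cell_km: float
    admin2_of_cell: np.ndarray   # (n_cells,) int
    admin1_of_admin2: np.ndarray  # (n_admin2,) int

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def n_admin2(self) -> int:
        return len(self.admin1_of_admin2)

    @property
    def n_admin1(self) -> int:
        return int(self.admin1_of_admin2.max()) + 1

    @property
    def admin1_of_cell(self) -> np.ndarray:
        return self.admin1_of_admin2[self.admin2_of_cell]

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) x/y coordinates of cell centers in km, row-major."""
        r, c = np.divmod(np.arange(self.n_cells), self.ncols)
        return np.column_stack(((c + 0.5) * self.cell_km, (r + 0.5) * self.cell_km))

    def extent_km(self) -> tuple[float, float]:
        return self.ncols * self.cell_km, self.nrows * self.cell_km

    def cells_in_admin2(self, a2: int) -> np.ndarray:
        return np.flatnonzero(self.admin2_of_cell == a2)

    def cells_in_admin1(self, a1: int) -> np.ndarray:
        return np.flatnonzero(self.admin1_of_cell == a1)

    def cell_of_xy(self, x_km: np.ndarray, y_km: np.ndarray) -> np.ndarray:
        """Map point coordinates to the containing cell index (clamped to grid)."""
        c = np.clip((np.asarray(x_km) / self.cell_km).astype(int), 0, self.ncols - 1)
        r = np.clip((np.asarray(y_km) / self.cell_km).astype(int), 0, self.nrows - 1)
        return r * self.ncols + c


def make_geography(nrows: int, ncols: int, cell_km: float = 5.0,
                   n_admin1: int = 2, admin2_per_admin1: int = 2) -> GeographySpec:
    """Partition the grid into ``n_admin1`` row bands, each split column-wise
    into ``admin2_per_admin1`` blocks.  The partition is exhaustive and disjoint
    by construction."""
    if nrows < 4 or ncols < 4:
        raise ValueError("grid must be at least 4x4")
    if n_admin1 < 2 or admin2_per_admin1 < 2:
        raise ValueError("need >= 2 admin1 units each containing >= 2 admin2 units")
    if nrows < n_admin1 or ncols < admin2_per_admin1:
        raise ValueError("more admin units than grid rows/cols")
    row_band = np.minimum((np.arange(nrows) * n_admin1) // nrows, n_admin1 - 1)
    col_block = np.minimum((np.arange(ncols) * admin2_per_admin1) // ncols,
                           admin2_per_admin1 - 1)
    a1 = np.repeat(row_band, ncols)
    a2 = a1 * admin2_per_admin1 + np.tile(col_block, nrows)
    admin1_of_admin2 = np.repeat(np.arange(n_admin1), admin2_per_admin1)
    return GeographySpec(nrows, ncols, cell_km, a2.astype(int), admin1_of_admin2)


# ---------------------------------------------------------------------------
# world config and containers


@dataclass
class FieldParams:
    """Generating parameters for one latent nested-indicator surface."""

    intercept: float
    betas: tuple[float, ...]          # one per covariate, logit scale
    spatial_range_km: float = 30.0
    spatial_sd: float = 0.4
    ar1: float = 0.85


def _default_field_params() -> dict[str, FieldParams]:
    # Operating point: national CPR in the 10-50% band typical of western and
    # eastern sub-Saharan countries; modern share of use high; need among
    # non-users ~25-35%; intent among in-need non-users ~45-65%.
    return {
        "any_use": FieldParams(-0.85, (0.30, -0.20, -0.25, 0.10, 0.40)),
        "modern_among_users": FieldParams(1.8, (0.10, -0.05, -0.15, 0.05, 0.20)),
        "need_among_nonusers": FieldParams(-0.85, (0.10, -0.10, -0.10, 0.05, 0.15)),
        "intent_among_inneed_nonusers": FieldParams(0.2, (0.15, -0.10, -0.15, 0.05, 0.25)),
    }


@dataclass
class WorldConfig:
    nrows: int = 20
    ncols: int = 20
    cell_km: float = 5.0
    n_admin1: int = 4
    admin2_per_admin1: int = 2
    years: tuple[int, ...] = tuple(range(2000, 2008))
    total_women: float = 2.0e6
    pop_growth: float = 0.015
    covariate_smooth_cells: float = 3.0
    covariate_year_drift: float = 0.15
    married_frac: float = 0.72
    married_logit_shift: float = 0.8  # any-use logit gap, ever-married vs never
    intent_12m_frac: float = 0.7      # P(intend within 12m | intend ever)
    field_params: dict[str, FieldParams] = field(default_factory=_default_field_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 4 or self.ncols < 4:
            raise ValueError("grid must be at least 4x4")
        years = tuple(self.years)
        if list(years) != list(range(years[0], years[-1] + 1)):
            raise ValueError("years must form a contiguous range")
        self.years = years


@dataclass
class World:
    """A generated synthetic country."""

    config: WorldConfig
    geo: GeographySpec
    years: tuple[int, ...]
    population: np.ndarray        # (n_years, n_cells) women 15-49
    covariates: np.ndarray        # (n_covariates, n_years, n_cells), standardised
    true_fields: dict[str, np.ndarray]       # indicator -> (n_years, n_cells) in (0,1)
    linear_predictor: dict[str, np.ndarray]  # logit-scale covariate part

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        if year not in self.years:
            raise ValueError(f"year {year} outside world range {self.years[0]}-{self.years[-1]}")
        return self.years.index(year)

    def true_admin_mean(self, indicator: str, level: str = "admin2") -> np.ndarray:
        """Population-weighted true prevalence per admin unit, (n_years, n_units)."""
        ids = self.geo.admin2_of_cell if level == "admin2" else self.geo.admin1_of_cell
        n_units = ids.max() + 1
        vals = self.true_fields[indicator]
        num = np.zeros((self.n_years, n_units))
        den = np.zeros((self.n_years, n_units))
        for u in range(n_units):
            m = ids == u
            num[:, u] = (vals[:, m] * self.population[:, m]).sum(axis=1)
            den[:, u] = self.population[:, m].sum(axis=1)
        return num / den


def _smooth_surface(rng: np.random.Generator, nrows: int, ncols: int,
                    sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian surface via filtered white noise."""
    z = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return (z / sd if sd > 0 else z).ravel()


def _matern_chol(geo: GeographySpec, range_km: float) -> np.ndarray:
    xy = geo.cell_centers()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    c = matern32(d, range_km)
    c[np.diag_indices_from(c)] += 1e-9
    return np.linalg.cholesky(c)


def _sample_st_gp(rng: np.random.Generator, chol_s: np.ndarray, n_years: int,
                  ar1: float, sd: float) -> np.ndarray:
    """Separable space-time GP draw: Matern-3/2 in space, stationary AR(1) in time."""
    n_cells = chol_s.shape[0]
    out = np.empty((n_years, n_cells))
    innov = chol_s @ rng.standard_normal((n_cells, n_years))
    out[0] = innov[:, 0]
    scale = np.sqrt(max(1.0 - ar1 ** 2, 0.0))
    for t in range(1, n_years):
        out[t] = ar1 * out[t - 1] + scale * innov[:, t]
    return sd * out


def generate_world(config: WorldConfig) -> World:
    """Generate geography, population, covariates and latent truth.

    Deterministic for a fixed config+seed.  With ``spatial_sd = 0`` the logit
    of each true field equals the covariate linear predictor exactly.
    """
    cfg = config
    geo = make_geography(cfg.nrows, cfg.ncols, cfg.cell_km,
                         cfg.n_admin1, cfg.admin2_per_admin1)
    rng = np.random.default_rng(cfg.seed)
    n_years, n_cells = len(cfg.years), geo.n_cells

    # population: smooth lognormal surface with mild exponential growth
    pop_base = np.exp(1.2 * _smooth_surface(rng, cfg.nrows, cfg.ncols,
                                            cfg.covariate_smooth_cells))
    pop = np.empty((n_years, n_cells))
    for t in range(n_years):
        surf = pop_base * (1.0 + cfg.pop_growth) ** t
        pop[t] = surf / surf.sum() * cfg.total_women * (1.0 + cfg.pop_growth) ** t

    # covariates: smooth base + per-year drift, standardised per year.
    # "population" covariate is the log of the population raster itself.
    cov = np.empty((len(COVARIATE_NAMES), n_years, n_cells))
    for k, name in enumerate(COVARIATE_NAMES):
        if name == "population":
            raw = np.log(pop)
        else:
            base = _smooth_surface(rng, cfg.nrows, cfg.ncols, cfg.covariate_smooth_cells)
            raw = np.empty((n_years, n_cells))
            for t in range(n_years):
                drift = cfg.covariate_year_drift * _smooth_surface(
                    rng, cfg.nrows, cfg.ncols, cfg.covariate_smooth_cells)
                raw[t] = base + drift
        mu = raw.mean(axis=1, keepdims=True)
        sd = raw.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        cov[k] = (raw - mu) / sd

    # latent nested fields (Matern Cholesky cached per range within this call)
    chol_cache: dict[float, np.ndarray] = {}
    true_fields: dict[str, np.ndarray] = {}
    linpred: dict[str, np.ndarray] = {}
    for name in NESTED_INDICATORS:
        fp = cfg.field_params[name]
        eta_cov = fp.intercept + np.tensordot(np.asarray(fp.betas), cov, axes=(0, 0))
        eta = eta_cov
        if fp.spatial_sd > 0:
            key = float(fp.spatial_range_km)
            if key not in chol_cache:
                chol_cache[key] = _matern_chol(geo, fp.spatial_range_km)
            eta = eta_cov + _sample_st_gp(rng, chol_cache[key], n_years,
                                          fp.ar1, fp.spatial_sd)
        linpred[name] = eta_cov      # covariate part only; GP excluded
        true_fields[name] = expit(eta)

    return World(cfg, geo, tuple(cfg.years), pop, cov, true_fields, linpred)


# ---------------------------------------------------------------------------
# survey simulation


@dataclass
class SurveyDesignSpec:
    """Design of one simulated survey."""

    year: int
    n_clusters: int = 30
    respondents_per_cluster: int = 25
    weight_sd: float = 0.3            # lognormal sigma of design-weight noise
    geocoding: str = "point"          # point | displaced-point | polygon-admin1 | polygon-admin2
    ever_married_only: bool = False
    missing_need_components: bool = False
    intent_12m_horizon: bool = False
    no_intent_question: bool = False

    def __post_init__(self) -> None:
        if self.n_clusters <= 0 or self.respondents_per_cluster <= 0:
            raise ValueError("cluster and respondent counts must be positive")
        if self.geocoding not in GEOCODING_MODES:
            raise ValueError(f"geocoding must be one of {GEOCODING_MODES}")
        if self.intent_12m_horizon and self.no_intent_question:
            raise ValueError("intent horizon set while no-intent-question set")

    def restriction_tags(self) -> str:
        tags = []
        if self.ever_married_only:
            tags.append("ever_married_only")
        if self.missing_need_components:
            tags.append("missing_need_components")
        if self.intent_12m_horizon:
            tags.append("intent_12m_horizon")
        if self.no_intent_question:
            tags.append("no_intent_question")
        return "|".join(tags)


def _marginal_preserving_shifts(l: np.ndarray, q: float, delta: float) -> np.ndarray:
    """Newton solve for a such that q*expit(l+a+delta) + (1-q)*expit(l+a) = expit(l).

    Returns ``a`` (the never-married logit offset); ever-married get ``a+delta``.
    Keeps the population marginal equal to the latent any-use field while
    giving ever-married women systematically higher use.
    """
    p = expit(l)
    a = np.full_like(l, -q * delta)
    for _ in range(30):
        pm, pu = expit(l + a + delta), expit(l + a)
        f = q * pm + (1 - q) * pu - p
        fp = q * pm * (1 - pm) + (1 - q) * pu * (1 - pu)
        a -= f / np.maximum(fp, 1e-12)
        if np.max(np.abs(f)) < 1e-12:
            break
    return a


_MODERN_CODES = ("pills", "condoms", "implant", "injection", "iud",
                 "female_sterilization")
_TRADITIONAL_CODES = ("rhythm", "withdrawal", "lam")


def _benign_fecund_fields(df: pd.DataFrame, idx: np.ndarray) -> None:
    """Fill fecundity-related items with values that pass every infecundity screen."""
    df.loc[idx, "sexually_active"] = True
    for m in ("cannot_have_children", "menopausal", "hysterectomy", "never_menstruated"):
        df.loc[idx, m] = False
    df.loc[idx, "years_married"] = 2.0
    df.loc[idx, "ever_used_contraception"] = True
    df.loc[idx, "ever_gave_birth"] = True
    df.loc[idx, "years_since_last_birth"] = 1.0
    df.loc[idx, "period_since_last_birth"] = True


def simulate_survey(world: World, design: SurveyDesignSpec, seed: int,
                    survey_id: str = "survey") -> pd.DataFrame:
    """Simulate one cluster survey as respondent-level microdata.

    Clusters are grid cells sampled proportional to population (with
    replacement); respondent outcomes are Bernoulli draws from the cell's true
    nested probabilities with the correct conditioning (modern use drawn only
    among users, need only among non-users, intent only among in-need
    non-users).  Questionnaire fields are constructed to be consistent with
    the indicator-derivation decision tree, so deriving indicators from the
    microdata recovers the simulated outcomes.
    """
    cfg = world.config
    t = world.year_index(design.year)
    rng = np.random.default_rng(seed)
    geo = world.geo

    pop = world.population[t]
    clusters = rng.choice(geo.n_cells, size=design.n_clusters, replace=True,
                          p=pop / pop.sum())
    m = design.respondents_per_cluster
    n = design.n_clusters * m
    cell = np.repeat(clusters, m)
    cluster_id = np.repeat(np.arange(design.n_clusters), m)

    ever_married = rng.random(n) < cfg.married_frac
    l_any = logit(np.clip(world.true_fields["any_use"][t], 1e-9, 1 - 1e-9))
    a = _marginal_preserving_shifts(l_any, cfg.married_frac, cfg.married_logit_shift)
    p_any = expit(l_any[cell] + a[cell] + cfg.married_logit_shift * ever_married)

    any_use = rng.random(n) < p_any
    modern = any_use & (rng.random(n) < world.true_fields["modern_among_users"][t][cell])
    need = ~any_use & (rng.random(n) < world.true_fields["need_among_nonusers"][t][cell])
    intent = (~any_use & need
              & (rng.random(n) < world.true_fields["intent_among_inneed_nonusers"][t][cell]))
    intent_12m = intent & (rng.random(n) < cfg.intent_12m_frac)

    df = pd.DataFrame({
        "survey_id": survey_id,
        "year": design.year,
        "cluster_id": cluster_id,
        "cell_true": cell,
        "admin1_id": geo.admin1_of_cell[cell],
        "admin2_id": geo.admin2_of_cell[cell],
        "age": rng.integers(15, 50, size=n),
        "ever_married": ever_married,
        "weight": np.exp(rng.normal(0.0, design.weight_sd, size=n)),
    })
    df["current_method"] = ""
    df["pregnancy_status"] = "neither"
    df["wantedness"] = ""
    df["fertility_pref"] = "wants_within_2y"
    df["sexually_active"] = True
    for c in ("cannot_have_children", "menopausal", "hysterectomy", "never_menstruated"):
        df[c] = False
    df["years_married"] = 2.0
    df["ever_used_contraception"] = True
    df["ever_gave_birth"] = True
    df["years_since_last_birth"] = 1.0
    df["period_since_last_birth"] = True

    # users: method code consistent with the modern/traditional draw
    users = np.flatnonzero(any_use)
    mod_users = np.flatnonzero(any_use & modern)
    trad_users = np.flatnonzero(any_use & ~modern)
    df.loc[mod_users, "current_method"] = rng.choice(_MODERN_CODES, size=len(mod_users))
    df.loc[trad_users, "current_method"] = rng.choice(_TRADITIONAL_CODES, size=len(trad_users))
    _benign_fecund_fields(df, users)

    # non-users in need: pregnancy/amenorrhea branches or fertility preference
    in_need = np.flatnonzero(~any_use & need)
    branch = rng.choice(6, size=len(in_need), p=[0.10, 0.05, 0.10, 0.35, 0.15, 0.25])
    preg = in_need[branch < 2]
    df.loc[preg, "pregnancy_status"] = "pregnant"
    df.loc[preg, "wantedness"] = np.where(branch[branch < 2] == 0, "later", "unwanted")
    ppa = in_need[branch == 2]
    df.loc[ppa, "pregnancy_status"] = "postpartum_amenorrheic"
    df.loc[ppa, "wantedness"] = "later"
    pref = in_need[branch >= 3]
    df.loc[pref, "fertility_pref"] = np.select(
        [branch[branch >= 3] == 3, branch[branch >= 3] == 4],
        ["wants_none", "undecided"], "wants_after_2y")
    _benign_fecund_fields(df, pref)
    # pregnant/amenorrheic women still answer the preference item
    df.loc[np.concatenate([preg, ppa]), "fertility_pref"] = np.where(
        rng.random(len(preg) + len(ppa)) < 0.15, "wants_within_2y", "wants_after_2y")

    # non-users not in need
    not_need = np.flatnonzero(~any_use & ~need)
    branch = rng.choice(6, size=len(not_need), p=[0.12, 0.08, 0.45, 0.15, 0.12, 0.08])
    preg = not_need[branch == 0]
    df.loc[preg, "pregnancy_status"] = "pregnant"
    df.loc[preg, "wantedness"] = "then"
    ppa = not_need[branch == 1]
    df.loc[ppa, "pregnancy_status"] = "postpartum_amenorrheic"
    df.loc[ppa, "wantedness"] = "then"
    df.loc[np.concatenate([preg, ppa]), "fertility_pref"] = np.where(
        rng.random(len(preg) + len(ppa)) < 0.35, "wants_within_2y", "wants_after_2y")
    soon = not_need[branch == 2]
    df.loc[soon, "fertility_pref"] = "wants_within_2y"
    _benign_fecund_fields(df, soon)
    inactive = not_need[branch == 3]
    df.loc[inactive, "sexually_active"] = False
    df.loc[inactive, "fertility_pref"] = "wants_after_2y"
    meno = not_need[branch == 4]
    df.loc[meno, "menopausal"] = True
    df.loc[meno, "fertility_pref"] = "wants_none"
    sterile = not_need[branch == 5]  # married >= 5y, never used, never gave birth
    df.loc[sterile, "years_married"] = 6.0
    df.loc[sterile, "ever_used_contraception"] = False
    df.loc[sterile, "ever_gave_birth"] = False
    df.loc[sterile, "fertility_pref"] = "wants_none"

    # intent items (answered by in-need non-users)
    df["intent_any"] = ""
    df["intent_12m"] = ""
    inn = ~any_use & need
    df.loc[inn, "intent_any"] = np.where(intent[inn], "yes", "no")
    df.loc[inn, "intent_12m"] = np.where(intent_12m[inn], "yes", "no")

    # --- questionnaire restrictions -------------------------------------
    if design.no_intent_question:
        df["intent_any"] = ""
        df["intent_12m"] = ""
    if design.intent_12m_horizon:
        df["intent_any"] = ""  # only the 12-month item exists
    if design.missing_need_components:
        df["wantedness"] = ""
        for c in ("cannot_have_children", "menopausal", "hysterectomy", "never_menstruated"):
            df[c] = np.nan
        df["years_married"] = np.nan
        df["ever_used_contraception"] = np.nan
        df["years_since_last_birth"] = np.nan
        df["period_since_last_birth"] = np.nan
    if design.ever_married_only:
        df = df[df["ever_married"]].reset_index(drop=True)

    # --- geocoding --------------------------------------------------------
    xy = geo.cell_centers()[df["cell_true"].to_numpy()]
    if design.geocoding in ("point", "displaced-point"):
        x, y = xy[:, 0].copy(), xy[:, 1].copy()
        if design.geocoding == "displaced-point":
            # one displacement per cluster, DHS-style: U(0,2km) for 99%,
            # U(0,5km) for 1%, uniform direction, never across the border
            cl = df["cluster_id"].to_numpy()
            ncl = design.n_clusters
            theta = rng.uniform(0, 2 * np.pi, size=ncl)
            dist = np.where(rng.random(ncl) < 0.99,
                            rng.uniform(0, 2.0, size=ncl),
                            rng.uniform(0, 5.0, size=ncl))
            ext_x, ext_y = geo.extent_km()
            dx, dy = dist * np.cos(theta), dist * np.sin(theta)
            x = np.clip(x + dx[cl], 0.0, ext_x - 1e-9)
            y = np.clip(y + dy[cl], 0.0, ext_y - 1e-9)
        df["x_km"], df["y_km"] = x, y
        df["polygon_level"], df["polygon_id"] = "", -1
    else:
        df["x_km"], df["y_km"] = np.nan, np.nan
        if design.geocoding == "polygon-admin1":
            df["polygon_level"] = "admin1"
            df["polygon_id"] = df["admin1_id"]
        else:
            df["polygon_level"] = "admin2"
            df["polygon_id"] = df["admin2_id"]

    df["tags"] = design.restriction_tags()
    return df


def config_to_dict(cfg: WorldConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["field_params"] = {k: dataclasses.asdict(v) for k, v in cfg.field_params.items()}
    d["years"] = list(cfg.years)
    return d


#: microdata column dictionary, written alongside saved worlds
MICRODATA_COLUMNS = {
    "survey_id": "survey identifier",
    "year": "survey year",
    "cluster_id": "sampled cluster (one grid cell) within the survey",
    "cell_true": "true grid-cell index of the cluster (diagnostics only)",
    "admin1_id": "admin1 unit of the cluster's true cell",
    "admin2_id": "admin2 unit of the cluster's true cell",
    "age": "age in completed years (15-49)",
    "ever_married": "ever married or in union (bool)",
    "weight": "design weight (positive; arbitrary scale)",
    "current_method": "contraceptive method code, empty if not using",
    "pregnancy_status": "pregnant | postpartum_amenorrheic | neither",
    "wantedness": "current/last pregnancy wanted: then | later | unwanted; "
                  "empty if inapplicable or item absent",
    "fertility_pref": "wants_within_2y | wants_after_2y | wants_none | undecided",
    "sexually_active": "sexually active (bool)",
    "cannot_have_children": "infecundity marker (bool)",
    "menopausal": "infecundity marker (bool)",
    "hysterectomy": "infecundity marker (bool)",
    "never_menstruated": "infecundity marker (bool)",
    "years_married": "years since first marriage",
    "ever_used_contraception": "ever used any method (bool)",
    "ever_gave_birth": "ever gave birth (bool)",
    "years_since_last_birth": "years since most recent birth",
    "period_since_last_birth": "had a period since before the last birth (bool)",
    "intent_any": "intends future contraceptive use, any horizon: yes | no; "
                  "empty if inapplicable or item absent",
    "intent_12m": "intends use within 12 months: yes | no; empty likewise",
    "x_km": "cluster x coordinate in km (NaN for polygon-geocoded surveys)",
    "y_km": "cluster y coordinate in km (NaN for polygon-geocoded surveys)",
    "polygon_level": "admin1 | admin2 for polygon-geocoded surveys, else empty",
    "polygon_id": "polygon unit id, -1 for point surveys",
    "tags": "pipe-separated survey design restriction tags",
}


def save_world(world: World, out_dir) -> None:
    """Write a world to disk: gridded arrays (NPZ, one array per
    covariate/field plus population, keyed by name), the admin assignment
    vectors, the generating configuration as YAML, and the microdata column
    dictionary as JSON."""
    import json
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {"population": world.population,
              "admin2_of_cell": world.geo.admin2_of_cell,
              "admin1_of_admin2": world.geo.admin1_of_admin2,
              "years": np.array(world.years)}
    for k, name in enumerate(COVARIATE_NAMES):
        arrays[f"covariate_{name}"] = world.covariates[k]
    for name, vals in world.true_fields.items():
        arrays[f"true_{name}"] = vals
        arrays[f"linpred_{name}"] = world.linear_predictor[name]
    np.savez_compressed(out / "world.npz", **arrays)
    with open(out / "world_config.yaml", "w") as f:
        yaml.safe_dump(config_to_dict(world.config), f, sort_keys=True)
    with open(out / "microdata_columns.json", "w") as f:
        json.dump(MICRODATA_COLUMNS, f, indent=2)
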