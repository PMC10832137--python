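"""Stage-2 Bayesian geostatistical model for one country-indicator.

Observations are cluster-level binomial aggregates (successes =
prevalence x n_eff, trials = n_eff, real-valued).  The logit-scale linear
predictor combines the three stage-1 stacker surfaces through a simplex
weight vector (softmax-parameterised, so stage-2 predictions stay inside the
stackers' convex hull) plus an intercept, and adds a latent space-time
random effect with separable covariance: Matern-3/2 in space; in time a
stationary AR(1) component plus a time-constant component (for persistent
local deviations from the covariate surfaces); plus an i.i.d. cell-year
nugget.

Inference is empirical-Bayes Laplace:

1. simplex weights by binomial maximum likelihood on the out-of-fold stacker
   predictions; the intercept is then recalibrated against the full-data
   refit surfaces actually used for prediction (out-of-fold and full-refit
   predictions can differ by a systematic offset which must not leak into
   the prediction surface);
2. field hyperparameters (spatial range and SD, AR(1) coefficient, nugget
   SD) by Gaussian marginal likelihood of the out-of-fold logit residuals —
   a GP-regression likelihood with known heteroscedastic binomial noise —
   initialised from a space-time variogram fit and softly shrunk toward
   prior medians; the curvature of this likelihood provides an asymptotic
   hyperparameter covariance;
3. the latent-field posterior mode and curvature (Laplace approximation) at
   the plug-in hyperparameters, using the exact Kronecker eigendecomposition
   of the prior covariance for fast conjugate-gradient solves;
4. posterior draws by Papandreou-Yuille perturbation sampling — exact draws
   from the Gaussian approximation without forming a dense precision — with
   hyperparameter uncertainty propagated by re-solving the mode for
   hyperparameter values resampled from their asymptotic distribution.

Out-of-fold residuals are used for hyperparameter estimation because
residuals against the full-data surfaces understate the field (the flexible
sub-models partially interpolate it in-sample); pseudo-points produced by
polygon resampling are excluded because they inherit their parent's
prevalence and split effective sample size, which misstates both their
differences and their sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular
from scipy.special import expit, logit

from .world import GeographySpec, matern32

_EPS = 1e-6


@dataclass
class GeostatPriors:
    """Hyperparameter bounds and shrinkage medians for the latent field.

    Units: range in km; SDs on the logit scale.  ``penalty`` scales the soft
    quadratic penalty (in log / atanh space) pulling the marginal-likelihood
    fit toward the medians; it matters only when the residuals are weakly
    informative.
    """

    range_bounds: tuple[float, float] = (5.0, 500.0)
    sd_bounds: tuple[float, float] = (1e-3, 3.0)
    ar1_bounds: tuple[float, float] = (-0.98, 0.98)
    nugget_bounds: tuple[float, float] = (1e-3, 2.0)
    static_bounds: tuple[float, float] = (1e-3, 3.0)
    range_median: float = 50.0
    sd_median: float = 0.5
    ar1_median: float = 0.8
    nugget_median: float = 0.15
    static_median: float = 0.15
    penalty: float = 1.0

    def transformed_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = _transform(self.range_bounds[0], self.sd_bounds[0],
                        self.ar1_bounds[0], self.nugget_bounds[0],
                        self.static_bounds[0])
        hi = _transform(self.range_bounds[1], self.sd_bounds[1],
                        self.ar1_bounds[1], self.nugget_bounds[1],
                        self.static_bounds[1])
        return lo, hi


@dataclass
class GeostatFit:
    """Fitted stage-2 model: simplex weights, hyperparameters, and the
    Laplace approximation (mode + curvature operator) of the latent field."""

    weights: np.ndarray            # simplex over sub-models
    intercept: float
    range_km: float
    spatial_sd: float
    ar1: float
    nugget_sd: float
    static_sd: float
    hyper_se: dict                 # approximate SEs (transformed scale)
    theta_hat: np.ndarray          # transformed hyperparameters at the optimum
    theta_cov: np.ndarray | None   # asymptotic covariance (transformed scale)
    eta_grid: np.ndarray           # (n_years, n_cells) fixed-effect logit surface
    mode: np.ndarray               # (n_cells, n_years) latent posterior mode
    obs_info: np.ndarray           # (n_cells, n_years) aggregated binomial curvature
    eig_s: tuple                   # (V_s, d_s) spatial eigendecomposition
    eig_t: tuple                   # (V_t, d_t) temporal eigendecomposition
    lam: np.ndarray                # (n_cells, n_years) prior eigenvalues
    geo: GeographySpec = None
    priors: GeostatPriors = field(default_factory=GeostatPriors)
    cells: np.ndarray = None       # observation bookkeeping, for hyper-draw refits
    tix: np.ndarray = None
    prev: np.ndarray = None
    n_eff: np.ndarray = None
    converged: bool = True
    n_newton: int = 0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.mode.shape[0]

    @property
    def n_years(self) -> int:
        return self.mode.shape[1]


# ---------------------------------------------------------------------------
# stage-2 fixed effects: simplex-weighted stacker combination


def _binom_loglik_eta(eta, prev, n_eff):
    p = np.clip(expit(eta), _EPS, 1 - _EPS)
    return (n_eff * (prev * np.log(p) + (1 - prev) * np.log1p(-p))).sum()


def fit_simplex_weights(oof_logit: np.ndarray, prev: np.ndarray,
                        n_eff: np.ndarray) -> tuple[np.ndarray, float]:
    """Binomial ML fit of softmax simplex weights + intercept on out-of-fold
    stacker logits."""
    k = oof_logit.shape[1]

    def unpack(theta):
        alpha, b = theta[:k], theta[k]
        w = np.exp(alpha - alpha.max())
        return w / w.sum(), b

    def negll(theta):
        w, b = unpack(theta)
        eta = b + oof_logit @ w
        return -_binom_loglik_eta(eta, prev, n_eff) + 1e-4 * (theta[:k] ** 2).sum()

    res = optimize.minimize(negll, np.zeros(k + 1), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    w, b = unpack(res.x)
    return w, float(b)




# ---------------------------------------------------------------------------
# hyperparameters: variogram initialiser + Gaussian marginal likelihood


def _transform(range_km, sd, ar1, nugget_sd, static_sd=None):
    out = [np.log(range_km), np.log(sd), np.arctanh(ar1), np.log(nugget_sd)]
    if static_sd is not None:
        out.append(np.log(static_sd))
    return np.array(out)


def _untransform(theta):
    vals = (np.exp(theta[0]), np.exp(theta[1]), np.tanh(theta[2]),
            np.exp(theta[3]))
    if len(theta) > 4:
        vals = vals + (np.exp(theta[4]),)
    return vals


def _hyper_dict(theta) -> dict:
    vals = _untransform(theta)
    out = {"range_km": float(vals[0]), "spatial_sd": float(vals[1]),
           "ar1": float(vals[2]), "nugget_sd": float(vals[3])}
    out["static_sd"] = float(vals[4]) if len(vals) > 4 else 0.0
    return out


def fit_variogram_hyperparameters(
        xy: np.ndarray, tix: np.ndarray, resid: np.ndarray, meas_var: np.ndarray,
        priors: GeostatPriors, n_dist_bins: int = 10, max_time_lag: int = 2,
        pair_group: np.ndarray | None = None) -> tuple[dict, dict]:
    """Estimate (range, spatial SD, AR1, nugget SD) by weighted least squares
    on the empirical space-time semivariogram of logit residuals.

    The expected half squared difference of two residuals at spatial lag h and
    time lag u is ``sigma^2 (1 - rho_m(h) phi^u) + tau^2 [h,u != 0] + (v_i+v_j)/2``
    where v are the known binomial measurement variances; the measurement part
    is subtracted pairwise before binning.

    ``pair_group`` marks artificially dependent observations (pseudo-points
    resampled from one polygon observation): such observations are excluded
    whenever enough genuine point observations remain, otherwise only
    same-parent pairs are dropped.
    """
    if pair_group is not None:
        is_pseudo = _nonempty_mask(pair_group)
        if (~is_pseudo).sum() >= 30:
            keep = ~is_pseudo
            xy, tix = xy[keep], tix[keep]
            resid, meas_var = resid[keep], meas_var[keep]
            pair_group = None
    n = len(resid)
    iu, ju = np.triu_indices(n, k=1)
    if pair_group is not None:
        grp = np.asarray(pair_group, dtype=object)
        dep = (grp[iu] == grp[ju]) & _nonempty_mask(grp)[iu]
        iu, ju = iu[~dep], ju[~dep]
    h = np.sqrt(((xy[iu] - xy[ju]) ** 2).sum(axis=1))
    u = np.abs(tix[iu] - tix[ju])
    g = 0.5 * (resid[iu] - resid[ju]) ** 2 - 0.5 * (meas_var[iu] + meas_var[ju])

    keep = u <= max_time_lag
    h, u, g = h[keep], u[keep], g[keep]
    hmax = np.quantile(h[h > 0], 0.7) if np.any(h > 0) else 1.0
    edges = np.linspace(0.0, hmax, n_dist_bins + 1)
    gh, gg, gw, gu = [], [], [], []
    for lag in range(max_time_lag + 1):
        # zero-distance pairs binned separately: at lag 0 they share the
        # cell-year nugget (gamma = 0); at lag > 0 they pin nugget + AR1
        m0 = (u == lag) & (h == 0)
        if m0.sum() >= 5:
            gh.append(0.0)
            gg.append(g[m0].mean())
            gw.append(np.sqrt(m0.sum()))
            gu.append(lag)
        for b in range(n_dist_bins):
            m = (u == lag) & (h > max(edges[b], 0)) & (h <= edges[b + 1])
            if m.sum() < 5:
                continue
            gh.append(h[m].mean())
            gg.append(g[m].mean())
            gw.append(np.sqrt(m.sum()))
            gu.append(lag)
    gh, gg, gw, gu = map(np.asarray, (gh, gg, gw, gu))
    if len(gh) < 4:
        raise ValueError("too few variogram bins; not enough observations")

    same_site = (gh == 0) & (gu == 0)
    pri = priors

    def model_gamma(theta):
        r, s, a, t = _untransform(theta)
        cov = s ** 2 * matern32(gh, r) * a ** np.abs(gu).astype(float)
        gam = s ** 2 + t ** 2 - cov
        return np.where(same_site, 0.0, gam)

    theta_pri = _transform(pri.range_median, pri.sd_median, pri.ar1_median,
                           pri.nugget_median)

    def residuals(theta):
        pen = np.sqrt(pri.penalty) * (theta - theta_pri)
        return np.concatenate([gw * (model_gamma(theta) - gg), pen])

    lo, hi = (b[:4] for b in pri.transformed_bounds())
    x0 = np.clip(theta_pri, lo, hi)
    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                 xtol=1e-10, ftol=1e-10)
    J = sol.jac
    dof = max(len(gh) - 4, 1)
    s2 = (sol.fun[:len(gh)] ** 2).sum() / dof
    try:
        cov_theta = s2 * np.linalg.inv(J.T @ J)
        se_theta = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
    except np.linalg.LinAlgError:
        se_theta = np.full(4, np.nan)
    ses = {"log_range": se_theta[0], "log_sd": se_theta[1],
           "atanh_ar1": se_theta[2], "log_nugget": se_theta[3]}
    return _hyper_dict(sol.x), ses


def _nonempty_mask(grp) -> np.ndarray:
    return np.array([g is not None and g == g and str(g) != ""
                     for g in np.asarray(grp, dtype=object)])


def fit_ml_hyperparameters(xy: np.ndarray, tix: np.ndarray, cells: np.ndarray,
                           resid: np.ndarray, meas_var: np.ndarray,
                           priors: GeostatPriors, x0: np.ndarray | None = None,
                           max_obs: int = 1200, seed: int = 0,
                           ) -> tuple[dict, np.ndarray, np.ndarray | None]:
    """Hyperparameters by Gaussian marginal likelihood of logit residuals.

    The residual vector is modelled as N(0, C) with
    ``C = R_matern(h) (sigma^2 phi^|dt| + sigma_static^2)
    + tau^2 [same cell-year] + diag(v)``, v the known binomial measurement
    variances.  The static component captures time-persistent local
    deviations from the covariate surfaces (e.g. stable stacker-surface
    error), which a single AR(1) cannot represent without biasing its
    persistence.  A soft quadratic penalty in the transformed parameters
    (log range, log SD, atanh AR1, log nugget, log static SD) pulls toward
    the prior medians.  Returns the estimates, the transformed optimum and
    its asymptotic covariance (inverse curvature, finite differences); the
    covariance is None when the curvature is not positive definite.
    """
    n = len(resid)
    if n > max_obs:
        idx = np.random.default_rng(seed).choice(n, max_obs, replace=False)
        xy, tix, cells = xy[idx], tix[idx], cells[idx]
        resid, meas_var = resid[idx], meas_var[idx]
        n = max_obs
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    dt = np.abs(tix[:, None] - tix[None, :]).astype(float)
    same_cy = (cells[:, None] == cells[None, :]) & (dt == 0)
    lo, hi = priors.transformed_bounds()
    theta_pri = np.clip(_transform(priors.range_median, priors.sd_median,
                                   priors.ar1_median, priors.nugget_median,
                                   priors.static_median), lo, hi)

    def nll(theta):
        theta = np.clip(theta, lo, hi)
        r, s, a, t, st = _untransform(theta)
        C = matern32(d, r) * (s ** 2 * a ** dt + st ** 2) \
            + t ** 2 * same_cy + np.diag(meas_var)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return 1e12
        z = solve_triangular(L, resid, lower=True)
        return (0.5 * (z ** 2).sum() + np.log(np.diag(L)).sum()
                + 0.5 * priors.penalty * ((theta - theta_pri) ** 2).sum())

    start = np.clip(x0 if x0 is not None else theta_pri, lo, hi)
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
    theta_hat = np.clip(res.x, lo, hi)

    # asymptotic covariance from finite-difference curvature
    k = len(theta_hat)
    step = 0.05
    H = np.zeros((k, k))
    f0 = nll(theta_hat)
    fp = np.array([nll(theta_hat + step * np.eye(k)[i]) for i in range(k)])
    fm = np.array([nll(theta_hat - step * np.eye(k)[i]) for i in range(k)])
    for i in range(k):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step ** 2
        for j in range(i + 1, k):
            fpp = nll(theta_hat + step * (np.eye(k)[i] + np.eye(k)[j]))
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / step ** 2
    theta_cov = None
    try:
        evals = np.linalg.eigvalsh(H)
        if evals.min() > 1e-8:
            theta_cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pass
    return _hyper_dict(theta_hat), theta_hat, theta_cov


# ---------------------------------------------------------------------------
# Kronecker prior algebra


def _ar1_corr(n_years: int, phi: float) -> np.ndarray:
    idx = np.arange(n_years)
    return phi ** np.abs(idx[:, None] - idx[None, :]).astype(float)


def build_prior_eig(geo: GeographySpec, n_years: int, range_km: float,
                    spatial_sd: float, ar1: float, nugget_sd: float,
                    static_sd: float = 0.0):
    """Eigendecomposition of the separable prior covariance
    Sigma_s (x) T + tau^2 I, with Matern-3/2 spatial correlation Sigma_s and
    temporal covariance ``T = sigma^2 AR1(phi) + sigma_static^2 J`` (an AR(1)
    component plus a time-constant component sharing the same spatial
    correlation).  Returns (V_s, d_s), (V_t, d_t) and the (n_cells, n_years)
    eigenvalue matrix."""
    xy = geo.cell_centers()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    sig_s = matern32(d, range_km)
    ds, Vs = np.linalg.eigh(sig_s)
    T = spatial_sd ** 2 * _ar1_corr(n_years, ar1) \
        + static_sd ** 2 * np.ones((n_years, n_years))
    dt, Vt = np.linalg.eigh(T)
    lam = np.outer(np.clip(ds, 0, None), np.clip(dt, 0, None)) + nugget_sd ** 2
    return (Vs, ds), (Vt, dt), np.maximum(lam, 1e-10)


def _apply_eig_weight(E, Vs, Vt, wmat):
    """(Vs (x) Vt) diag(wmat) (Vs (x) Vt)' applied to E (n_cells, n_years[, m])."""
    if E.ndim == 2:
        return Vs @ ((Vs.T @ E @ Vt) * wmat) @ Vt.T
    Z = np.einsum("ci,cym->iym", Vs, E)
    Z = np.einsum("iym,yj->ijm", Z, Vt)
    Z = Z * wmat[:, :, None]
    Z = np.einsum("ci,ijm->cjm", Vs, Z)
    return np.einsum("cjm,yj->cym", Z, Vt)


def _apply_Q(U, Vs, Vt, lam):
    """Prior precision applied to U (n_cells, n_years[, m])."""
    return _apply_eig_weight(U, Vs, Vt, 1.0 / lam)


def _pcg(apply_A, B, apply_Minv, tol=1e-8, maxiter=400):
    """Preconditioned conjugate gradients for (possibly batched) RHS B."""
    X = np.zeros_like(B)
    R = B.copy()
    Z = apply_Minv(R)
    P = Z.copy()
    rz = (R * Z).sum(axis=(0, 1)) if B.ndim == 3 else (R * Z).sum()
    b_norm = np.sqrt((B * B).sum())
    if b_norm == 0:
        return X, 0
    for it in range(maxiter):
        AP = apply_A(P)
        denom = (P * AP).sum(axis=(0, 1)) if B.ndim == 3 else (P * AP).sum()
        alpha = rz / np.maximum(denom, 1e-300)
        X = X + alpha * P
        R = R - alpha * AP
        if np.sqrt((R * R).sum()) < tol * b_norm:
            return X, it + 1
        Z = apply_Minv(R)
        rz_new = (R * Z).sum(axis=(0, 1)) if B.ndim == 3 else (R * Z).sum()
        beta = rz_new / np.maximum(rz, 1e-300)
        P = Z + beta * P
        rz = rz_new
    warnings.warn("PCG reached maxiter without full convergence", stacklevel=2)
    return X, maxiter


def _newton_mode(cells, tix, prev, n_eff, eta_obs, Vs, Vt, lam, shape,
                 U0=None, maxiter=50):
    """Damped Newton maximisation of the latent-field posterior at fixed
    hyperparameters.  Returns (mode, obs curvature, iterations)."""
    nc, ny = shape
    U = np.zeros((nc, ny)) if U0 is None else U0.copy()

    def scatter(vals):
        M = np.zeros((nc, ny))
        np.add.at(M, (cells, tix), vals)
        return M

    def objective(Umat):
        ll = _binom_loglik_eta(eta_obs + Umat[cells, tix], prev, n_eff)
        return ll - 0.5 * (Umat * _apply_Q(Umat, Vs, Vt, lam)).sum()

    obj = objective(U)
    gnorm = np.inf
    for it in range(maxiter):
        pi = np.clip(expit(eta_obs + U[cells, tix]), _EPS, 1 - _EPS)
        grad = scatter(n_eff * (prev - pi)) - _apply_Q(U, Vs, Vt, lam)
        Wobs = scatter(n_eff * pi * (1 - pi))
        dbar = Wobs.sum() / Wobs.size
        minv_w = 1.0 / (1.0 / lam + dbar)

        step, _ = _pcg(lambda M: _apply_Q(M, Vs, Vt, lam) + Wobs * M, grad,
                       lambda M: _apply_eig_weight(M, Vs, Vt, minv_w), tol=1e-9)
        alpha = 1.0
        for _ in range(20):
            U_new = U + alpha * step
            obj_new = objective(U_new)
            if obj_new >= obj - 1e-12:
                break
            alpha *= 0.5
        gnorm = np.sqrt((grad * grad).sum())
        U, obj = U_new, obj_new
        if gnorm < 1e-6 * max(1.0, n_eff.sum()) \
                or np.sqrt((step * step).sum()) * alpha < 1e-8:
            pi = np.clip(expit(eta_obs + U[cells, tix]), _EPS, 1 - _EPS)
            return U, scatter(n_eff * pi * (1 - pi)), it + 1
    raise RuntimeError(
        f"Laplace Newton failed to converge after {maxiter} iterations "
        f"(|grad| = {gnorm:.3g})")


# ---------------------------------------------------------------------------
# fitting and drawing


def fit_geostat(cells: np.ndarray, tix: np.ndarray, prev: np.ndarray,
                n_eff: np.ndarray, oof_logit: np.ndarray,
                surfaces: np.ndarray, geo: GeographySpec, n_years: int,
                priors: GeostatPriors | None = None, seed: int = 0,
                pair_group: np.ndarray | None = None) -> GeostatFit:
    """Fit the stage-2 model for one indicator.

    Parameters
    ----------
    cells, tix : observation cell index and year index on the prediction grid.
    prev, n_eff : observation prevalence and effective sample size.
    oof_logit : (n_obs, n_submodels) out-of-fold stacker logits.
    surfaces : (n_submodels, n_years, n_cells) full-data stacker surfaces.
    pair_group : optional resampling parent ids; pseudo-point observations
        are excluded from hyperparameter estimation.
    """
    priors = priors or GeostatPriors()
    cells = np.asarray(cells, int)
    tix = np.asarray(tix, int)
    prev = np.asarray(prev, float)
    n_eff = np.asarray(n_eff, float)
    if len(prev) == 0:
        raise ValueError("need at least one observation")
    if cells.min() < 0 or cells.max() >= geo.n_cells:
        raise ValueError("observations outside the prediction grid")
    if tix.min() < 0 or tix.max() >= n_years:
        raise ValueError("observations outside the modelled year range")

    # 1. fixed effects: simplex weights on out-of-fold logits, intercept
    # recalibrated against the full-data refit surfaces
    w, b_oof = fit_simplex_weights(oof_logit, prev, n_eff)
    surf_logit_obs = logit(surfaces)[:, tix, cells].T @ w
    b = float(optimize.minimize_scalar(
        lambda bb: -_binom_loglik_eta(bb + surf_logit_obs, prev, n_eff),
        bounds=(-10, 10), method="bounded").x)
    eta_grid = b + np.tensordot(w, logit(surfaces), axes=(0, 0))
    eta_obs = eta_grid[tix, cells]

    # 2. hyperparameters from out-of-fold working residuals
    p_cc = np.clip(prev, 1.0 / (2 * np.maximum(n_eff, 1.0)),
                   1.0 - 1.0 / (2 * np.maximum(n_eff, 1.0)))
    resid = logit(p_cc) - (b_oof + oof_logit @ w)
    meas_var = 1.0 / (n_eff * p_cc * (1 - p_cc))
    xy = geo.cell_centers()[cells]

    keep = np.ones(len(prev), bool)
    if pair_group is not None:
        is_pseudo = _nonempty_mask(pair_group)
        if (~is_pseudo).sum() >= 30:
            keep = ~is_pseudo
    try:
        hv, _ = fit_variogram_hyperparameters(xy, tix, resid, meas_var, priors,
                                              pair_group=pair_group)
        x0 = _transform(hv["range_km"], hv["spatial_sd"], hv["ar1"],
                        hv["nugget_sd"], priors.static_median)
    except ValueError:
        x0 = None
    hyper, theta_hat, theta_cov = fit_ml_hyperparameters(
        xy[keep], tix[keep], cells[keep], resid[keep], meas_var[keep],
        priors, x0=x0, seed=seed)
    hyper_se = {}
    if theta_cov is not None:
        se = np.sqrt(np.clip(np.diag(theta_cov), 0, None))
        hyper_se = {"log_range": se[0], "log_sd": se[1], "atanh_ar1": se[2],
                    "log_nugget": se[3], "log_static": se[4]}

    # 2b. recalibrate the intercept marginalising over the latent prior
    # variance (Gauss-Hermite): the reported point estimate is the draw mean
    # E[expit(eta + u)], which exceeds expit(eta) below one half, so an
    # intercept matched to expit(eta) alone would bias the draw means
    v_lat = (hyper["spatial_sd"] ** 2 + hyper["static_sd"] ** 2
             + hyper["nugget_sd"] ** 2)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(21)
    gh_w = gh_w / gh_w.sum()

    def negll_b_marg(bb):
        pbar = (gh_w[None, :] * expit(bb + surf_logit_obs[:, None]
                                      + np.sqrt(v_lat) * gh_x[None, :])).sum(1)
        pbar = np.clip(pbar, _EPS, 1 - _EPS)
        return -(n_eff * (prev * np.log(pbar)
                          + (1 - prev) * np.log1p(-pbar))).sum()

    b = float(optimize.minimize_scalar(negll_b_marg, bounds=(-10, 10),
                                       method="bounded").x)
    eta_grid = b + np.tensordot(w, logit(surfaces), axes=(0, 0))
    eta_obs = eta_grid[tix, cells]

    # 3. Laplace approximation at the plug-in hyperparameters
    eig_s, eig_t, lam = build_prior_eig(geo, n_years, hyper["range_km"],
                                        hyper["spatial_sd"], hyper["ar1"],
                                        hyper["nugget_sd"], hyper["static_sd"])
    Vs, _ = eig_s
    Vt, _ = eig_t
    U, Wobs, n_newton = _newton_mode(cells, tix, prev, n_eff, eta_obs,
                                     Vs, Vt, lam, (geo.n_cells, n_years))

    return GeostatFit(weights=w, intercept=b, range_km=hyper["range_km"],
                      spatial_sd=hyper["spatial_sd"], ar1=hyper["ar1"],
                      nugget_sd=hyper["nugget_sd"],
                      static_sd=hyper["static_sd"], hyper_se=hyper_se,
                      theta_hat=theta_hat, theta_cov=theta_cov,
                      eta_grid=eta_grid, mode=U, obs_info=Wobs,
                      eig_s=eig_s, eig_t=eig_t, lam=lam, geo=geo,
                      priors=priors, cells=cells, tix=tix, prev=prev,
                      n_eff=n_eff, converged=True, n_newton=n_newton, seed=seed)


def _perturbation_draws(rng, m, mode, eta_grid, Vs, Vt, lam, Wobs):
    """m exact draws from N(mode, (Q + W)^{-1}), pushed through the link."""
    nc, ny = mode.shape
    dbar = Wobs.sum() / Wobs.size
    minv_w = 1.0 / (1.0 / lam + dbar)
    e1 = rng.standard_normal((nc, ny, m))
    e2 = rng.standard_normal((nc, ny, m))
    B = _apply_eig_weight(e1, Vs, Vt, lam ** -0.5) + np.sqrt(Wobs)[:, :, None] * e2
    X, _ = _pcg(lambda M: _apply_Q(M, Vs, Vt, lam) + Wobs[:, :, None] * M, B,
                lambda M: _apply_eig_weight(M, Vs, Vt, minv_w), tol=1e-7)
    eta = eta_grid.T[:, :, None] + mode[:, :, None] + X
    return np.clip(expit(eta), _EPS, 1 - _EPS).transpose(2, 1, 0)


def draw_surfaces(fit: GeostatFit, n_draws: int, seed: int,
                  hyper_uncertainty: bool = True,
                  n_hyper_batches: int = 8) -> np.ndarray:
    """Draw probability surfaces from the Laplace approximation.

    Latent-field draws use perturbation sampling: ``x = mode + (Q + W)^{-1}
    (Q^{1/2} e1 + W^{1/2} e2)`` with independent standard normal e1, e2,
    which has exactly the covariance ``(Q + W)^{-1}`` of the Gaussian
    approximation.  When the hyperparameter curvature is available and
    ``hyper_uncertainty`` is set, draws are produced in batches, each batch
    conditioning on hyperparameters resampled from their asymptotic normal
    distribution (with the mode re-solved per batch), so that uncertainty in
    range, SD, AR(1) and nugget propagates into the surfaces.  Identical
    seeds give identical draws; returns (n_draws, n_years, n_cells) values
    strictly inside (0, 1).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if not fit.converged:
        raise RuntimeError("cannot draw from a non-converged fit")
    rng = np.random.default_rng(seed)
    Vs, _ = fit.eig_s
    Vt, _ = fit.eig_t
    nc, ny = fit.n_cells, fit.n_years

    use_hyper = (hyper_uncertainty and fit.theta_cov is not None
                 and fit.cells is not None and n_hyper_batches >= 2
                 and n_draws >= 2 * n_hyper_batches)
    if not use_hyper:
        out = np.empty((n_draws, ny, nc))
        for start in range(0, n_draws, 64):
            m = min(64, n_draws - start)
            out[start:start + m] = _perturbation_draws(
                rng, m, fit.mode, fit.eta_grid, Vs, Vt, fit.lam, fit.obs_info)
        return out

    lo, hi = fit.priors.transformed_bounds()
    k = len(fit.theta_hat)
    try:
        Lth = np.linalg.cholesky(fit.theta_cov + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError:
        Lth = np.diag(np.sqrt(np.clip(np.diag(fit.theta_cov), 0, None)))
    eta_obs = fit.eta_grid[fit.tix, fit.cells]
    sizes = np.full(n_hyper_batches, n_draws // n_hyper_batches)
    sizes[:n_draws % n_hyper_batches] += 1
    out = np.empty((n_draws, ny, nc))
    pos = 0
    for bsize in sizes:
        theta = np.clip(fit.theta_hat + Lth @ rng.standard_normal(k), lo, hi)
        hy = _hyper_dict(theta)
        eig_s, eig_t, lam = build_prior_eig(fit.geo, ny, hy["range_km"],
                                            hy["spatial_sd"], hy["ar1"],
                                            hy["nugget_sd"], hy["static_sd"])
        Vs_b, _ = eig_s
        Vt_b, _ = eig_t
        U, Wobs, _ = _newton_mode(fit.cells, fit.tix, fit.prev, fit.n_eff,
                                  eta_obs, Vs_b, Vt_b, lam, (nc, ny),
                                  U0=fit.mode)
        out[pos:pos + bsize] = _perturbation_draws(
            rng, bsize, U, fit.eta_grid, Vs_b, Vt_b, lam, Wobs)
        pos += bsize
    return out


def predict_mode(fit: GeostatFit) -> np.ndarray:
    """Plug-in posterior-mode probability surface, (n_years, n_cells)."""
    return np.clip(expit(fit.eta_grid + fit.mode.T), _EPS, 1 - _EPS)
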