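"""Stage-1 stacked generalisation: three covariate sub-models per indicator.

Three sub-models are fitted to cluster-level binomial observations
(successes = prevalence x n_eff, trials = n_eff) on the five standardised
covariates:

* a B-spline additive logistic model (smooth nonlinear main effects);
* an L2-penalised (ridge) logistic regression, penalty chosen by an internal
  validation split;
* gradient-boosted trees (depth 3, learning rate 0.05, tree count by early
  stopping).

Out-of-fold predictions are produced under K-fold cross-validation with
folds blocked by the admin1 unit of each observation, guarding against
spatial leakage; full-data refits produce prediction surfaces for every
cell-year.  The out-of-fold predictions are what the stage-2 geostatistical
model uses to estimate its combination weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lightgbm as lgb
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer

_CLIP = 1e-6

SUBMODEL_NAMES = ("spline_additive", "ridge", "boosted_trees")


@dataclass
class StackerConfig:
    folds: int = 5
    ridge_c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    spline_knots: int = 7           # basis dimension ~ knots + degree - 1 per covariate
    spline_c: float = 1.0
    gbt_max_trees: int = 200
    gbt_depth: int = 3
    gbt_learning_rate: float = 0.05
    gbt_early_stopping: int = 20


def _expand_binomial(X: np.ndarray, prev: np.ndarray, n_eff: np.ndarray):
    """Fractional binomial data as weighted 0/1 rows for sklearn/lightgbm."""
    X2 = np.vstack([X, X])
    y2 = np.concatenate([np.ones(len(X)), np.zeros(len(X))])
    w2 = np.concatenate([prev * n_eff, (1.0 - prev) * n_eff])
    keep = w2 > 0
    return X2[keep], y2[keep], w2[keep]


class _InterceptModel:
    """Fallback when outcomes are degenerate: predicts the weighted mean."""

    def __init__(self, p: float):
        self.p = float(np.clip(p, _CLIP, 1 - _CLIP))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.p)


class _SklearnWrapper:
    def __init__(self, est):
        self.est = est

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.est.predict_proba(X)[:, 1]


class _LgbWrapper:
    def __init__(self, booster):
        self.booster = booster

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.booster.predict(X))


def _weighted_logloss(p: np.ndarray, prev: np.ndarray, n_eff: np.ndarray) -> float:
    p = np.clip(p, _CLIP, 1 - _CLIP)
    return float(-(n_eff * (prev * np.log(p) + (1 - prev) * np.log(1 - p))).sum()
                 / n_eff.sum())


def _fit_ridge(X, prev, n_eff, cfg: StackerConfig, seed: int):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    cut = max(int(0.75 * len(X)), 1)
    tr, va = idx[:cut], idx[cut:]
    best_c, best_loss = cfg.ridge_c_grid[0], np.inf
    if len(va) >= 5 and len(cfg.ridge_c_grid) > 1:
        for c in cfg.ridge_c_grid:
            est = LogisticRegression(C=c, max_iter=2000)
            Xt, yt, wt = _expand_binomial(X[tr], prev[tr], n_eff[tr])
            est.fit(Xt, yt, sample_weight=wt)
            loss = _weighted_logloss(est.predict_proba(X[va])[:, 1], prev[va], n_eff[va])
            if loss < best_loss:
                best_c, best_loss = c, loss
    est = LogisticRegression(C=best_c, max_iter=2000)
    X2, y2, w2 = _expand_binomial(X, prev, n_eff)
    est.fit(X2, y2, sample_weight=w2)
    return _SklearnWrapper(est)


def _fit_spline(X, prev, n_eff, cfg: StackerConfig, seed: int):
    est = make_pipeline(
        SplineTransformer(n_knots=cfg.spline_knots, degree=3,
                          extrapolation="linear"),
        LogisticRegression(C=cfg.spline_c, max_iter=2000))
    X2, y2, w2 = _expand_binomial(X, prev, n_eff)
    est.fit(X2, y2, **{"logisticregression__sample_weight": w2})
    return _SklearnWrapper(est)


def _fit_gbt(X, prev, n_eff, cfg: StackerConfig, seed: int):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    cut = max(int(0.8 * len(X)), 1)
    tr, va = idx[:cut], idx[cut:]
    Xt, yt, wt = _expand_binomial(X[tr], prev[tr], n_eff[tr])
    params = dict(objective="binary", max_depth=cfg.gbt_depth, num_leaves=8,
                  learning_rate=cfg.gbt_learning_rate, min_child_samples=10,
                  n_jobs=1, deterministic=True, force_row_wise=True,
                  seed=int(seed) % (2 ** 31), verbosity=-1)
    train_set = lgb.Dataset(Xt, label=yt, weight=wt)
    callbacks = []
    valid_sets = None
    if len(va) >= 10 and cfg.gbt_max_trees > 1:
        Xv, yv, wv = _expand_binomial(X[va], prev[va], n_eff[va])
        valid_sets = [lgb.Dataset(Xv, label=yv, weight=wv, reference=train_set)]
        callbacks = [lgb.early_stopping(cfg.gbt_early_stopping, verbose=False)]
    booster = lgb.train(params, train_set, num_boost_round=cfg.gbt_max_trees,
                        valid_sets=valid_sets, callbacks=callbacks)
    return _LgbWrapper(booster)


_FITTERS = {"spline_additive": _fit_spline, "ridge": _fit_ridge,
            "boosted_trees": _fit_gbt}


@dataclass
class StackerEnsemble:
    names: tuple[str, ...]
    models: dict[str, object]          # full-data refits
    oof_pred: np.ndarray               # (n_obs, n_submodels) probabilities
    fold_of_obs: np.ndarray            # (n_obs,) fold assignment used
    kept_covariates: np.ndarray        # column indices retained
    config: StackerConfig = field(default_factory=StackerConfig)
    seed: int = 0


def _weighted_mean(prev, n_eff):
    return float((prev * n_eff).sum() / n_eff.sum())


def _fit_one(name, X, prev, n_eff, cfg, seed):
    if np.allclose(prev, prev[0]):
        warnings.warn("all outcomes identical; intercept-only fallback", stacklevel=2)
        return _InterceptModel(_weighted_mean(prev, n_eff))
    return _FITTERS[name](X, prev, n_eff, cfg, seed)


def fit_stackers(X: np.ndarray, prev: np.ndarray, n_eff: np.ndarray,
                 block_id: np.ndarray, config: StackerConfig | None = None,
                 seed: int = 0) -> StackerEnsemble:
    """Fit the three sub-models with blocked out-of-fold predictions.

    Parameters
    ----------
    X : (n_obs, n_covariates) standardised covariate values at each
        observation's cell-year.
    prev, n_eff : observation prevalences and effective sample sizes.
    block_id : spatial block (admin1 id) per observation; folds group blocks.
    """
    cfg = config or StackerConfig()
    X = np.asarray(X, float)
    prev = np.asarray(prev, float)
    n_eff = np.asarray(n_eff, float)
    if len(X) < 20:
        raise ValueError("need at least 20 observations to fit stackers")

    var = X.var(axis=0)
    kept = np.flatnonzero(var > 1e-12)
    if len(kept) < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - len(kept)} zero-variance covariate(s)",
                      stacklevel=2)
    if len(kept) == 0:
        raise ValueError("all covariates degenerate")
    X = X[:, kept]

    blocks = np.unique(block_id)
    n_folds = min(cfg.folds, len(blocks)) if len(blocks) > 1 else min(cfg.folds, len(X))
    rng = np.random.default_rng(seed)
    if len(blocks) > 1:
        perm = rng.permutation(len(blocks))
        fold_of_block = {b: perm[i] % n_folds for i, b in enumerate(blocks)}
        fold = np.array([fold_of_block[b] for b in block_id])
    else:
        fold = rng.permutation(len(X)) % n_folds
    # blocked folds can be too unbalanced on very small data: fall back to
    # random folds rather than training a sub-model on a handful of points
    train_sizes = [(fold != f).sum() for f in range(n_folds)]
    if min(train_sizes) < 10:
        warnings.warn("spatially blocked folds too unbalanced; "
                      "falling back to random folds", stacklevel=2)
        fold = rng.permutation(len(X)) % n_folds

    oof = np.full((len(X), len(SUBMODEL_NAMES)), np.nan)
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        if te.sum() == 0:
            continue
        if tr.sum() < 10:
            raise ValueError("fold with fewer than 10 training observations")
        for j, name in enumerate(SUBMODEL_NAMES):
            m = _fit_one(name, X[tr], prev[tr], n_eff[tr], cfg, seed + 31 * f + j)
            oof[te, j] = m.predict(X[te])
    oof = np.clip(oof, _CLIP, 1 - _CLIP)

    models = {name: _fit_one(name, X, prev, n_eff, cfg, seed + 997 + j)
              for j, name in enumerate(SUBMODEL_NAMES)}
    return StackerEnsemble(SUBMODEL_NAMES, models, oof, fold, kept, cfg, seed)


def predict_stackers(ensemble: StackerEnsemble,
                     covariates: np.ndarray) -> np.ndarray:
    """Predict the three sub-model surfaces for every cell-year.

    ``covariates`` is the (n_covariates, n_years, n_cells) stack; returns
    (n_submodels, n_years, n_cells) probabilities, strictly inside (0, 1).
    Deterministic given the fitted ensemble.
    """
    if not np.all(np.isfinite(covariates)):
        bad = np.argwhere(~np.isfinite(covariates))
        raise ValueError(f"non-finite covariate values at indices {bad[:5].tolist()}")
    n_cov, n_years, n_cells = covariates.shape
    out = np.empty((len(ensemble.names), n_years, n_cells))
    for t in range(n_years):
        Xg = covariates[ensemble.kept_covariates, t, :].T
        for j, name in enumerate(ensemble.names):
            out[j, t] = ensemble.models[name].predict(Xg)
    return np.clip(out, _CLIP, 1 - _CLIP)
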