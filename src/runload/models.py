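"""Prediction models: elastic-net linear regression and gradient boosting.

Two model families link the Fourier/anthropometric predictors to peak
tissue forces:

* elastic net — penalized linear regression with mixing parameter
  ``alpha`` (0 = ridge, 1 = lasso) and strength ``lambda`` chosen by
  10-fold cross-validation over a log-spaced path, glmnet-style:
  minimize (1/2n)||y - Xb||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2)
  on standardized predictors, coefficients reported on the original scale;
* gradient-boosted regression trees (XGBoost) — shallow trees of depth
  3 or 6, learning rate 0.1 or 0.3, with the number of trees chosen by
  5-fold cross-validation; remaining booster parameters stay at their
  library defaults.

Tuning grids in replication mode: alpha in {0, 0.5, 1}; depth in {3, 6}
and learning rate in {0.1, 0.3}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from .cohort import derive_seed

ENET_ALPHA_GRID = (0.0, 0.5, 1.0)
GBT_DEPTH_GRID = (3, 6)
GBT_LEARNING_RATE_GRID = (0.1, 0.3)


class SchemaMismatchError(ValueError):
    """Prediction input columns do not match the training schema."""


@dataclass(frozen=True)
class ElasticNetSpec:
    """Elastic-net tuning: mixing alpha, strength lambda ('cv' = CV path)."""

    alpha: float = 1.0
    lam: Union[float, str] = "cv"
    cv_folds: int = 10
    standardize: bool = True
    n_lambdas: int = 100
    lambda_decades: float = 4.0
    #: coordinate-descent tolerance; loose enough for fast repeated
    #: refits, tight enough that the CV curve's argmin is stable
    tol: float = 1e-3
    max_iter: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if isinstance(self.lam, str) and self.lam != "cv":
            raise ValueError("lam must be a number or 'cv'")
        if not isinstance(self.lam, str) and self.lam < 0:
            raise ValueError("lam must be non-negative")

    @property
    def label(self) -> str:
        return f"enet a={self.alpha:g}"


@dataclass(frozen=True)
class GbtSpec:
    """Boosting tuning: depth, learning rate, tree count ('cv' = CV)."""

    depth: int = 3
    learning_rate: float = 0.1
    n_trees: Union[int, str] = "cv"
    cv_folds: int = 5
    #: cap on boosting rounds searched by CV, a desk-scale default
    max_trees: int = 80
    early_stopping_rounds: int = 8

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be at least 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if isinstance(self.n_trees, str) and self.n_trees != "cv":
            raise ValueError("n_trees must be a count or 'cv'")

    @property
    def label(self) -> str:
        return f"xgb d={self.depth} eta={self.learning_rate:g}"


@dataclass
class FittedModel:
    """A trained predictor bound to its training column schema."""

    family: str                      # 'elastic_net' | 'gbt'
    spec: object
    columns: list
    intercept: float = 0.0
    coef: Optional[np.ndarray] = None       # original predictor scale
    coef_std: Optional[np.ndarray] = None   # standardized predictor scale
    lambda_: Optional[float] = None
    booster: Optional[xgb.Booster] = None
    n_trees: Optional[int] = None
    constant_target: bool = False

    def to_json_dict(self) -> dict:
        """Portable summary (elastic net fully; boosters dump separately)."""
        out = {
            "family": self.family,
            "columns": list(self.columns),
            "intercept": float(self.intercept),
            "constant_target": self.constant_target,
        }
        if self.coef is not None:
            out["coef"] = [float(c) for c in self.coef]
            out["lambda"] = self.lambda_
        if self.n_trees is not None:
            out["n_trees"] = int(self.n_trees)
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _standardize(X: np.ndarray):
    """Center and scale columns; constant columns get unit scale."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _fold_indices(n: int, k: int, seed: int) -> list:
    """K roughly equal folds from a seeded permutation of the rows."""
    perm = np.random.default_rng(seed).permutation(n)
    return [perm[i::k] for i in range(k)]


def _lambda_path(Xs: np.ndarray, yc: np.ndarray, spec: ElasticNetSpec) -> np.ndarray:
    """Log-spaced path from lambda_max down ``lambda_decades`` decades.

    lambda_max is the smallest penalty that zeroes every slope for the
    lasso part; for alpha near 0 the usual glmnet convention of dividing by
    a small floor keeps the path finite.
    """
    n = Xs.shape[0]
    denom = max(spec.alpha, 1e-3)
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * denom)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max),
                       np.log10(lam_max) - spec.lambda_decades,
                       spec.n_lambdas)


def _ridge_path_coefs(Xc: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Ridge solutions for all penalties at once via one SVD.

    Solves argmin (1/2n)||y - Xb||^2 + (lam/2)||b||^2, i.e.
    b = (X'X + n lam I)^-1 X'y, for every lam; returns (p, n_lams).
    """
    n = Xc.shape[0]
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    uty = u.T @ yc
    # shrinkage factor per singular value and penalty
    d = s[:, None] / (s[:, None] ** 2 + n * lams[None, :])
    return vt.T @ (d * uty[:, None])


def _enet_solve(Xs: np.ndarray, yc: np.ndarray, alpha: float, lam: float,
                seed: int) -> np.ndarray:
    """Single elastic-net solution on standardized, centered data."""
    if lam == 0.0:
        return np.linalg.lstsq(Xs, yc, rcond=None)[0]
    if alpha == 0.0:
        return _ridge_path_coefs(Xs, yc, np.array([lam]))[:, 0]
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                       precompute=Xs.T @ Xs, max_iter=20000, tol=1e-7,
                       random_state=seed)
    model.fit(Xs, yc)
    return model.coef_.copy()


def _enet_cv_lambda(Xs: np.ndarray, yc: np.ndarray, spec: ElasticNetSpec,
                    seed: int):
    """Choose lambda minimizing the K-fold mean squared prediction error.

    Ties (within floating-point equality) resolve to the largest lambda,
    favouring parsimony.  Returns (lambda, path, mean CV error per path
    point).
    """
    path = _lambda_path(Xs, yc, spec)
    folds = _fold_indices(Xs.shape[0], spec.cv_folds, seed)
    n = Xs.shape[0]
    errors = np.zeros((len(folds), path.size))
    for i, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = Xs[mask], yc[mask]
        Xte, yte = Xs[test_idx], yc[test_idx]
        # re-center inside the fold so the no-intercept path is unbiased
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xtr, ytr = Xtr - xm, ytr - ym
        Xte = Xte - xm
        if spec.alpha == 0.0:
            coefs = _ridge_path_coefs(Xtr, ytr, path)
        else:
            Xtr = np.asfortranarray(Xtr)
            with warnings.catch_warnings():
                # the loose path tolerance trades exactness of low-penalty
                # path points for repeated-refit throughput; the CV argmin
                # is insensitive to it
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = enet_path(Xtr, ytr, l1_ratio=spec.alpha,
                                        alphas=path, max_iter=spec.max_iter,
                                        tol=spec.tol, precompute=Xtr.T @ Xtr,
                                        Xy=Xtr.T @ ytr, check_input=False)
        pred = Xte @ coefs + ym
        errors[i] = np.mean((pred - yte[:, None]) ** 2, axis=0)
    mean_err = errors.mean(axis=0)
    best = int(np.argmin(mean_err))  # first minimum = largest lambda
    return float(path[best]), path, mean_err


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_elastic_net(X, y, spec: ElasticNetSpec = ElasticNetSpec(),
                    seed: int = 0) -> FittedModel:
    """Fit an elastic net, choosing lambda by CV when ``spec.lam == 'cv'``.

    Predictors are standardized before penalization and coefficients are
    reported on the original scale (``coef_std`` keeps the standardized
    ones for effect-size ranking).  A constant target yields an
    intercept-only model flagged ``constant_target``.
    """
    Xm, columns = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of rows")
    if Xm.shape[0] < spec.cv_folds and spec.lam == "cv":
        raise ValueError("need at least cv_folds rows for cross-validation")

    y_mean = y.mean()
    if np.std(y) == 0.0:
        return FittedModel(family="elastic_net", spec=spec, columns=columns,
                           intercept=float(y_mean),
                           coef=np.zeros(Xm.shape[1]),
                           coef_std=np.zeros(Xm.shape[1]),
                           lambda_=None, constant_target=True)

    if spec.standardize:
        Xs, x_mean, x_sd = _standardize(Xm)
    else:
        Xs = Xm - Xm.mean(axis=0)
        x_mean, x_sd = Xm.mean(axis=0), np.ones(Xm.shape[1])
    yc = y - y_mean

    if spec.lam == "cv":
        lam, _, _ = _enet_cv_lambda(Xs, yc, spec, derive_seed(seed, "enet-cv"))
    else:
        lam = float(spec.lam)

    coef_std = _enet_solve(Xs, yc, spec.alpha, lam, derive_seed(seed, "enet"))
    coef = coef_std / x_sd
    intercept = y_mean - float(coef @ x_mean)
    return FittedModel(family="elastic_net", spec=spec, columns=columns,
                       intercept=intercept, coef=coef, coef_std=coef_std,
                       lambda_=lam)


def fit_gbt(X, y, spec: GbtSpec = GbtSpec(), seed: int = 0) -> FittedModel:
    """Fit gradient-boosted trees, choosing the tree count by CV.

    Uses squared-error boosting with the base score at the target mean.
    When ``spec.n_trees == 'cv'`` the round count minimizing the K-fold
    test RMSE is chosen (smallest count on ties).
    """
    Xm, columns = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of rows")
    if Xm.shape[0] < spec.cv_folds and spec.n_trees == "cv":
        raise ValueError("need at least cv_folds rows for cross-validation")

    params = {
        "max_depth": int(spec.depth),
        "eta": float(spec.learning_rate),
        "objective": "reg:squarederror",
        "base_score": float(y.mean()),
        "tree_method": "hist",
        "max_bin": 32,
        "nthread": 1,
        "seed": derive_seed(seed, "gbt"),
    }
    dtrain = xgb.DMatrix(Xm, label=y, feature_names=columns)
    if spec.n_trees == "cv":
        cv = xgb.cv(params, dtrain, num_boost_round=spec.max_trees,
                    nfold=spec.cv_folds, metrics="rmse",
                    seed=derive_seed(seed, "gbt-cv"), shuffle=True,
                    early_stopping_rounds=spec.early_stopping_rounds)
        n_trees = int(np.argmin(cv["test-rmse-mean"].to_numpy()) + 1)
    else:
        n_trees = int(spec.n_trees)
    booster = xgb.train(params, dtrain, num_boost_round=n_trees)
    return FittedModel(family="gbt", spec=spec, columns=columns,
                       booster=booster, n_trees=n_trees,
                       intercept=float(y.mean()),
                       constant_target=bool(np.std(y) == 0.0))


def predict(model: FittedModel, X_new) -> np.ndarray:
    """Apply a fitted model to new rows with the training schema.

    Raises :class:`SchemaMismatchError` naming offending columns when the
    input schema differs from the training one.
    """
    if isinstance(X_new, pd.DataFrame):
        new_cols = list(X_new.columns)
        missing = [c for c in model.columns if c not in X_new.columns]
        extra = [c for c in new_cols if c not in model.columns]
        if missing or extra:
            raise SchemaMismatchError(
                f"schema mismatch: missing {missing}, unexpected {extra}")
        Xm = X_new[model.columns].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.shape[1] != len(model.columns):
            raise SchemaMismatchError(
                f"expected {len(model.columns)} columns, got {Xm.shape[1]}")
    if model.family == "elastic_net":
        return model.intercept + Xm @ model.coef
    dm = xgb.DMatrix(Xm, feature_names=model.columns)
    return model.booster.predict(dm, iteration_range=(0, model.n_trees))


def staged_train_errors(model: FittedModel, X, y) -> np.ndarray:
    """Training MSE after each boosting round (diagnostic for monotonicity)."""
    if model.family != "gbt":
        raise ValueError("staged errors are defined for boosted models only")
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    dm = xgb.DMatrix(Xm, feature_names=model.columns)
    errs = []
    for i in range(1, model.n_trees + 1):
        pred = model.booster.predict(dm, iteration_range=(0, i))
        errs.append(np.mean((pred - y) ** 2))
    return np.asarray(errs)


def gain_importance(model: FittedModel) -> dict:
    """Per-feature total gain of a boosted model (0 for unused features)."""
    if model.family != "gbt":
        raise ValueError("gain importance is defined for boosted models only")
    raw = model.booster.get_score(importance_type="total_gain")
    return {c: float(raw.get(c, 0.0)) for c in model.columns}
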