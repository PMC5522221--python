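"""Log-linear and epsilon-SVR models of log-expression, with 10-fold CV.

The log-linear model is ordinary least squares,

    log2(L_i + sigma) = nu + sum_k alpha_k a'_ik + sum_l beta_l b'_il,

on the logged association features; the non-linear alternative is epsilon-SVR
with an RBF kernel (libsvm via scikit-learn), features standardized per
training fold. Predictive power is reported as the squared Pearson
correlation between out-of-fold predictions and observations (CV-R^2), the
model-agnostic convention; 1 - SS_res/SS_tot is computed alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import (
    AlignmentError,
    CollinearityError,
    ConfigError,
    DegenerateSampleError,
    UndefinedCorrelationError,
)


@dataclass
class ModelConfig:
    """Hyperparameters shared by every model fit in a run."""

    folds: int = 10
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    svr_gamma: object = "scale"  # 1 / (n_features * feature variance)
    grid_search: bool = False
    grid_c: tuple = (0.1, 1.0, 10.0)
    grid_gamma_factors: tuple = (0.25, 1.0, 4.0)
    r2_definition: str = "squared_pcc"  # or "coefficient_of_determination"


@dataclass
class ModelReport:
    """Fit + cross-validation summary for one feature set."""

    model_kind: str
    feature_names: list
    predictions_oof: np.ndarray
    predictions_full: np.ndarray
    observed: np.ndarray
    r2: float
    cv_r2: float
    pcc: float
    per_fold: list
    stability_rmse: float
    fold_assignment_seed: int
    coefficients: dict | None = None
    extras: dict = field(default_factory=dict)


def evaluate(predictions: np.ndarray, y: np.ndarray) -> tuple:
    """(r2, pcc) with r2 = pcc^2, the squared correlation of predicted vs
    observed values."""
    predictions = np.asarray(predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if predictions.shape != y.shape:
        raise AlignmentError(
            f"length mismatch: {predictions.shape} vs {y.shape}"
        )
    if predictions.size < 3:
        raise DegenerateSampleError("need at least 3 observations")
    if np.ptp(predictions) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    pcc = float(stats.pearsonr(predictions, y).statistic)
    return pcc ** 2, pcc


def coefficient_of_determination(predictions: np.ndarray, y: np.ndarray) -> float:
    """1 - SS_res/SS_tot; can be negative for poor out-of-sample predictions."""
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - predictions) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def stability_rmse(per_fold) -> float:
    """Root-mean-square gap between per-fold train and test R^2 — small means
    the model generalizes as well as it fits."""
    per_fold = list(per_fold)
    if len(per_fold) < 1:
        raise ConfigError("need at least one fold")
    gaps = np.array([tr - te for tr, te in per_fold], dtype=float)
    return float(np.sqrt(np.mean(gaps ** 2)))


def _as_matrix(X) -> tuple:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _check_design(X: np.ndarray, names, y: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise AlignmentError(f"X {X.shape} does not match y {y.shape}")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ConfigError("missing or non-finite values in X or y")
    if X.shape[0] <= X.shape[1] + 1:
        raise DegenerateSampleError("need n_genes > n_features + 1")
    A = np.column_stack([np.ones(X.shape[0]), X])
    _, r, piv = linalg.qr(A, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(A.shape) * np.finfo(float).eps
    rank = int(np.sum(d > tol))
    if rank < A.shape[1]:
        bad = sorted(names[j - 1] for j in piv[rank:] if j > 0)
        raise CollinearityError(f"collinear feature columns: {bad}", columns=bad)


def _folds(n: int, folds: int, seed: int):
    return list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(np.arange(n)))


def _ols_predict(Xtr, ytr, Xte):
    A = np.column_stack([np.ones(len(Xtr)), Xtr])
    beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    return np.column_stack([np.ones(len(Xte)), Xte]) @ beta, beta


def _cv_report(kind, X, names, y, folds, seed, fit_predict, coefficients, extras):
    if folds > len(y):
        warnings.warn(
            f"reducing folds from {folds} to {len(y)} (one gene per fold)",
            stacklevel=3,
        )
        folds = len(y)
    oof = np.empty_like(y)
    per_fold = []
    for tr, te in _folds(len(y), folds, seed):
        pred_te, pred_tr = fit_predict(X[tr], y[tr], X[te])
        oof[te] = pred_te
        try:
            tr_r2, _ = evaluate(pred_tr, y[tr])
        except (DegenerateSampleError, UndefinedCorrelationError):
            tr_r2 = np.nan
        try:
            te_r2, _ = evaluate(pred_te, y[te])
        except (DegenerateSampleError, UndefinedCorrelationError):
            te_r2 = np.nan
        per_fold.append((tr_r2, te_r2))
    full_pred, _ = fit_predict(X, y, X)
    r2, _ = evaluate(full_pred, y)
    cv_r2, pcc = evaluate(oof, y)
    finite = [(a, b) for a, b in per_fold if np.isfinite(b)]
    extras = dict(extras)
    extras["cv_cod"] = coefficient_of_determination(oof, y)
    extras["full_cod"] = coefficient_of_determination(full_pred, y)
    return ModelReport(
        model_kind=kind,
        feature_names=list(names),
        predictions_oof=oof,
        predictions_full=full_pred,
        observed=np.asarray(y, dtype=float),
        r2=r2,
        cv_r2=cv_r2,
        pcc=pcc,
        per_fold=per_fold,
        stability_rmse=stability_rmse(finite) if finite else float("nan"),
        fold_assignment_seed=seed,
        coefficients=coefficients,
        extras=extras,
    )


def fit_log_linear(X, y, folds: int = 10, seed: int = 0) -> ModelReport:
    """OLS fit of log-expression on (logged) association features.

    Coefficients come from the full-data fit; CV-R^2 and PCC from out-of-fold
    predictions under a seeded 10-fold split.
    """
    y = np.asarray(y, dtype=float)
    Xm, names = _as_matrix(X)
    _check_design(Xm, names, y)

    def fit_predict(Xtr, ytr, Xte):
        pred_te, _ = _ols_predict(Xtr, ytr, Xte)
        pred_tr, _ = _ols_predict(Xtr, ytr, Xtr)
        return pred_te, pred_tr

    _, beta = _ols_predict(Xm, y, Xm)
    coefficients = {"intercept": float(beta[0])}
    coefficients.update({n: float(b) for n, b in zip(names, beta[1:])})
    return _cv_report("log_linear", Xm, names, y, folds, seed, fit_predict, coefficients, {})


def _make_svr(cfg: ModelConfig) -> SVR:
    return SVR(kernel="rbf", C=cfg.svr_c, epsilon=cfg.svr_epsilon, gamma=cfg.svr_gamma)


def fit_svr(X, y, folds: int = 10, seed: int = 0, kernel_cfg: ModelConfig | None = None) -> ModelReport:
    """Epsilon-SVR (RBF kernel) fit with per-training-fold standardization.

    Hyperparameters default to C=1, epsilon=0.1, gamma='scale'; an optional
    inner-CV grid search over C and gamma can be enabled in ``kernel_cfg``.
    Deterministic given data, seed and hyperparameters.
    """
    cfg = kernel_cfg or ModelConfig(folds=folds)
    y = np.asarray(y, dtype=float)
    Xm, names = _as_matrix(X)
    _check_design(Xm, names, y)
    if np.ptp(y) == 0:
        raise DegenerateSampleError("constant response: SVR fit is degenerate")

    hyper = {"C": cfg.svr_c, "epsilon": cfg.svr_epsilon, "gamma": cfg.svr_gamma}
    if cfg.grid_search:
        hyper = _grid_search(Xm, y, cfg, seed)

    def fit_predict(Xtr, ytr, Xte):
        pipe = make_pipeline(
            StandardScaler(),
            SVR(kernel="rbf", C=hyper["C"], epsilon=hyper["epsilon"], gamma=hyper["gamma"]),
        )
        pipe.fit(Xtr, ytr)
        return pipe.predict(Xte), pipe.predict(Xtr)

    return _cv_report("svr", Xm, names, y, folds, seed, fit_predict, None, {"hyperparameters": hyper})


def _grid_search(Xm, y, cfg: ModelConfig, seed: int) -> dict:
    """3-fold inner grid search maximizing out-of-fold PCC."""
    scaler = StandardScaler().fit(Xm)
    Xs = scaler.transform(Xm)
    gamma0 = 1.0 / (Xm.shape[1] * Xs.var())
    best, best_pcc = None, -np.inf
    for c in cfg.grid_c:
        for gf in cfg.grid_gamma_factors:
            gamma = gamma0 * gf
            oof = np.empty_like(y)
            for tr, te in _folds(len(y), 3, seed):
                pipe = make_pipeline(
                    StandardScaler(), SVR(kernel="rbf", C=c, epsilon=cfg.svr_epsilon, gamma=gamma)
                )
                pipe.fit(Xm[tr], y[tr])
                oof[te] = pipe.predict(Xm[te])
            _, pcc = evaluate(oof, y)
            if pcc > best_pcc:
                best_pcc, best = pcc, {"C": c, "epsilon": cfg.svr_epsilon, "gamma": gamma}
    return best
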