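"""Calibration models: PLS, PCR, GRNN and epsilon-SVR, plus cross-validation.

Linear baselines (PLS, PCR) operate on column-centered data only, matching
common chemometric practice.  The distance-based models (GRNN, SVR)
standardize predictors to unit variance — learned on the calibration data
and frozen — because Euclidean distances across wavelengths are otherwise
dominated by high-variance bands; SVR additionally standardizes the target
so its epsilon-tube width has a stable meaning.

GRNN is Nadaraya-Watson kernel regression with a Gaussian kernel: the
"network" stores the training points and predicts

    yhat(x) = sum_i y_i w_i / sum_i w_i,  w_i = exp(-||x - x_i||^2 / (2 s^2))

with a single smoothing parameter s (the spread).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.svm import SVR

__all__ = [
    "CalibrationModel",
    "pls_fit",
    "pcr_fit",
    "select_n_latent",
    "grnn_predict",
    "grnn_fit",
    "svr_fit",
    "predict",
    "cross_validate",
]


@dataclass
class CalibrationModel:
    """A fitted predictor with its hyperparameters and frozen scaling."""

    kind: str  # pls | pcr | grnn | svr
    hyperparameters: dict
    _predict: Callable[[np.ndarray], np.ndarray]
    state: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._predict(np.atleast_2d(np.asarray(X, dtype=float)))


def predict(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def _check_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have inconsistent sample counts")
    if np.ptp(y) == 0:
        raise ValueError("target values are constant")
    return X, y


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------


def pls_fit(X: np.ndarray, y: np.ndarray, n_latent: int) -> CalibrationModel:
    """NIPALS partial least squares on column-centered data."""
    X, y = _check_xy(X, y)
    if not 1 <= n_latent <= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"n_latent={n_latent} outside 1..min(n-1, p)="
            f"{min(X.shape[0] - 1, X.shape[1])}"
        )
    est = PLSRegression(n_components=n_latent, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual may become tiny
        est.fit(X, y)
    return CalibrationModel(
        kind="pls",
        hyperparameters={"n_latent": n_latent},
        _predict=lambda Q: est.predict(Q).ravel(),
        state={"estimator": est},
    )


def pcr_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> CalibrationModel:
    """Principal component regression: PCA scores of centered X, then OLS."""
    X, y = _check_xy(X, y)
    if not 1 <= n_components <= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components outside 1..min(n-1, p)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    design = np.column_stack([np.ones(scores.shape[0]), scores])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)

    def _pred(Q: np.ndarray) -> np.ndarray:
        s = pca.transform(Q)
        return beta[0] + s @ beta[1:]

    return CalibrationModel(
        kind="pcr",
        hyperparameters={"n_components": n_components},
        _predict=_pred,
    )


def select_n_latent(
    X: np.ndarray,
    y: np.ndarray,
    max_latent: int = 15,
    n_folds: int = 5,
    seed: int = 0,
    kind: str = "pls",
) -> int:
    """Pick the latent-variable count minimizing RMSECV over 1..max_latent."""
    X, y = _check_xy(X, y)
    cap = min(max_latent, X.shape[0] - 2, X.shape[1])
    fitter = pls_fit if kind == "pls" else pcr_fit
    best_k, best = 1, np.inf
    for k in range(1, cap + 1):
        res = cross_validate(
            lambda A, b, k=k: fitter(A, b, min(k, A.shape[0] - 1, A.shape[1])),
            X, y, n_folds, seed,
        )
        if res["cvmse"] < best:
            best_k, best = k, res["cvmse"]
    return best_k


# ---------------------------------------------------------------------------
# GRNN
# ---------------------------------------------------------------------------


def grnn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    spread: float,
) -> np.ndarray:
    """Gaussian-kernel regression over stored training points.

    Numerically stabilized by subtracting the per-query max exponent; if all
    kernel weights underflow anyway the nearest neighbour's target is used.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    train_y = np.asarray(train_y, dtype=float).ravel()
    d2 = (
        np.sum(query_X**2, axis=1)[:, None]
        + np.sum(train_X**2, axis=1)[None, :]
        - 2.0 * query_X @ train_X.T
    )
    np.maximum(d2, 0.0, out=d2)
    expo = -d2 / (2.0 * spread**2)
    shift = expo.max(axis=1, keepdims=True)
    w = np.exp(expo - shift)
    denom = w.sum(axis=1)
    out = (w @ train_y) / denom
    dead = ~np.isfinite(out)
    if np.any(dead):  # pragma: no cover - extreme underflow path
        warnings.warn("GRNN weights underflowed; falling back to nearest neighbour")
        out[dead] = train_y[np.argmin(d2[dead], axis=1)]
    return out


def grnn_fit(X: np.ndarray, y: np.ndarray, spread: float) -> CalibrationModel:
    """GRNN with predictors standardized by the training mean/sd."""
    X, y = _check_xy(X, y)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    return CalibrationModel(
        kind="grnn",
        hyperparameters={"spread": spread},
        _predict=lambda Q: grnn_predict(Z, y, (Q - mu) / sd, spread),
    )


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------


def svr_fit(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    g: float,
    epsilon: float = 0.01,
) -> CalibrationModel:
    """Epsilon-insensitive support-vector regression with RBF kernel
    k(u, v) = exp(-g ||u - v||^2); predictors and target standardized."""
    if C <= 0 or g <= 0 or epsilon < 0:
        raise ValueError("require C > 0, g > 0, epsilon >= 0")
    X, y = _check_xy(X, y)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    y_mu, y_sd = y.mean(), y.std(ddof=0)
    est = SVR(kernel="rbf", C=C, gamma=g, epsilon=epsilon, tol=1e-6)
    est.fit((X - mu) / sd, (y - y_mu) / y_sd)
    return CalibrationModel(
        kind="svr",
        hyperparameters={"C": C, "g": g, "epsilon": epsilon},
        _predict=lambda Q: est.predict((Q - mu) / sd) * y_sd + y_mu,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _fold_assignment(n: int, n_folds: int, seed: int, keys=None) -> np.ndarray:
    """Deterministic fold labels; when sample keys are given the assignment
    is derived from the sorted keys so it is invariant to row order."""
    rng = np.random.default_rng(seed)
    if keys is None:
        perm = rng.permutation(n)
    else:
        keys = np.asarray(keys)
        if keys.size != n:
            raise ValueError("keys length must match n")
        order = np.argsort(keys, kind="stable")  # canonical order
        perm = order[rng.permutation(n)]
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def cross_validate(
    fit_fn: Callable[[np.ndarray, np.ndarray], CalibrationModel],
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    keys=None,
) -> dict:
    """K-fold cross-validation of a model factory.

    Returns ``cvmse`` (mean over folds of the fold MSE), ``rmsecv`` =
    sqrt(cvmse) and the per-fold MSEs.  All preprocessing internal to
    ``fit_fn`` is re-learned inside each training fold, so no statistics leak
    from held-out samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not 2 <= n_folds <= n:
        raise ValueError("n_folds must lie in 2..n")
    folds = _fold_assignment(n, n_folds, seed, keys)
    fold_mse = []
    for f in range(n_folds):
        test = folds == f
        if not test.any():
            raise ValueError(f"fold {f} is empty")
        model = fit_fn(X[~test], y[~test])
        pred = model.predict(X[test]) if hasattr(model, "predict") else model(X[test])
        fold_mse.append(float(np.mean((y[test] - np.asarray(pred).ravel()) ** 2)))
    cvmse = float(np.mean(fold_mse))
    return {"cvmse": cvmse, "rmsecv": float(np.sqrt(cvmse)), "fold_mse": fold_mse}
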