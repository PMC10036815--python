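"""Wavelength (feature-variable) selection for spectral calibration.

Four established strategies are implemented against a common result type:

* UVE  — uninformative variable elimination: real variables must beat the
  PLS-coefficient reliability of appended artificial noise variables.
* CARS — competitive adaptive reweighted sampling: Monte-Carlo PLS runs with
  an exponentially decreasing forced-retention ratio plus adaptive
  reweighted sampling; the iteration subset with minimal RMSECV wins.
* SPA  — successive projections algorithm: forward selection maximizing the
  projection of candidate columns onto the orthogonal complement of the
  selected set, scored by validation RMSE of a multiple linear regression.
* IRIV — iteratively retains informative variables: binary-matrix sampling
  classifies variables as strongly/weakly informative versus uninformative
  or interfering through the shift in RMSECV between rows that include and
  rows that exclude them; the losers are dropped, the procedure repeats, and
  a final backward elimination polishes the survivors.

All methods are deterministic under their seed and return sorted in-bounds
indices.  Ties in variable weights are broken toward the lower index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import calibrate
from .core import SpectraDataset

__all__ = [
    "SelectionResult",
    "correlation_map",
    "uve",
    "cars",
    "spa",
    "iriv",
    "reduction_percent",
]


@dataclass
class SelectionResult:
    method: str
    selected: np.ndarray
    history: pd.DataFrame
    params: dict
    seed: int

    def __post_init__(self) -> None:
        self.selected = np.asarray(sorted(set(int(i) for i in self.selected)))
        if self.selected.size == 0:
            raise ValueError("empty selection")

    def wavelengths(self, grid: np.ndarray) -> np.ndarray:
        """Selected band positions in nm on a given grid."""
        return np.asarray(grid)[self.selected]


def correlation_map(dataset: SpectraDataset) -> np.ndarray:
    """Pearson correlation between every pair of wavelength columns
    (the 2-D correlation spectrum).  Constant columns yield NaN rows."""
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation map")
    if dataset.mode != "absorbance":
        raise ValueError("correlation map is defined on log(1/R) spectra")
    X = dataset.spectra
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return corr


def _default_latent(X: np.ndarray, y: np.ndarray, n_latent, seed: int) -> int:
    if n_latent is not None:
        return int(n_latent)
    return calibrate.select_n_latent(X, y, max_latent=15, n_folds=5, seed=seed)


def _pls_coef(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    k = max(1, min(k, X.shape[0] - 1, X.shape[1]))
    model = calibrate.pls_fit(X, y, k)
    # regression vector of the centered model
    return np.asarray(model.state["estimator"].coef_).ravel()


def _rmsecv(X, y, k, n_folds, seed) -> float:
    k = max(1, min(k, X.shape[0] - 1 - X.shape[0] // n_folds, X.shape[1]))
    res = calibrate.cross_validate(
        lambda A, b: calibrate.pls_fit(A, b, min(k, A.shape[0] - 1, A.shape[1])),
        X, y, n_folds=n_folds, seed=seed,
    )
    return res["rmsecv"]


# ---------------------------------------------------------------------------
# UVE
# ---------------------------------------------------------------------------


def uve(
    X: np.ndarray,
    y: np.ndarray,
    n_latent: int | None = None,
    noise_scale: float = 1e-10,
    cutoff_quantile: float = 0.99,
    seed: int = 0,
) -> SelectionResult:
    """Uninformative variable elimination.

    Appends p artificial uniform-noise variables, runs leave-one-out PLS and
    computes the reliability c_j = mean(b_j) / sd(b_j) of every regression
    coefficient; real variables survive only if |c_j| exceeds the
    ``cutoff_quantile`` of |c| over the noise block.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("UVE needs at least 10 samples")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(size=(n, p)) * noise_scale
    Z = np.hstack([X, noise])
    k = _default_latent(X, y, n_latent, seed)
    coefs = np.empty((n, 2 * p))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        coefs[i] = _pls_coef(Z[mask], y[mask], k)
    sd = coefs.std(axis=0, ddof=1)
    mean = coefs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = mean / sd
    degenerate = sd == 0
    if degenerate.any():
        import warnings

        warnings.warn("UVE: zero coefficient spread; reliability set to +inf")
        c[degenerate] = np.inf
    cutoff = float(np.quantile(np.abs(c[p:]), cutoff_quantile))
    selected = np.flatnonzero(np.abs(c[:p]) > cutoff)
    if selected.size == 0:
        selected = np.array([int(np.argmax(np.abs(c[:p])))])
    history = pd.DataFrame(
        [{"iteration": 0, "subset_size": int(selected.size), "rmsecv": _rmsecv(X[:, selected], y, k, 5, seed)}]
    )
    return SelectionResult(
        method="uve",
        selected=selected,
        history=history,
        params={
            "n_latent": k,
            "noise_scale": noise_scale,
            "cutoff_quantile": cutoff_quantile,
            "cutoff": cutoff,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------


def cars_retention_ratio(i: int, n_runs: int, p: int) -> float:
    """Exponentially decreasing forced retention ratio r_i with the boundary
    conditions r_1 = 1 and r_N = 2/p."""
    if p < 3 or n_runs < 2:
        raise ValueError("need p >= 3 and n_runs >= 2")
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)
    return float(a * np.exp(-k * i))


def cars_forced_count(i: int, n_runs: int, p: int) -> int:
    """Number of variables the EDF forces at iteration i: ceil(r_i * p), with
    a tolerance so the r_N * p = 2 endpoint survives floating point."""
    return max(2, int(np.ceil(cars_retention_ratio(i, n_runs, p) * p - 1e-9)))


def cars(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    n_latent: int | None = None,
    sample_ratio: float = 0.8,
    n_cv: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    k = _default_latent(X, y, n_latent, seed)
    support = np.arange(p)
    best = {"rmsecv": np.inf, "selected": support}
    rows = []
    for i in range(1, n_runs + 1):
        draw = rng.choice(n, size=int(np.ceil(sample_ratio * n)), replace=False)
        coef = _pls_coef(X[np.ix_(draw, support)], y[draw], k)
        weights = np.abs(coef)
        # enforced exponential reduction, then adaptive reweighted sampling
        n_keep = min(cars_forced_count(i, n_runs, p), support.size)
        order = np.lexsort((np.arange(support.size), -weights))  # ties -> lower index
        support = support[np.sort(order[:n_keep])]
        weights = weights[np.sort(order[:n_keep])]
        if weights.sum() > 0 and support.size > 2:
            probs = weights / weights.sum()
            drawn = rng.choice(support.size, size=support.size, replace=True, p=probs)
            support = support[np.unique(drawn)]
        rmsecv = _rmsecv(X[:, support], y, k, n_cv, seed + i)
        rows.append({"iteration": i, "subset_size": int(support.size), "rmsecv": rmsecv})
        if rmsecv < best["rmsecv"]:
            best = {"rmsecv": rmsecv, "selected": support.copy()}
    return SelectionResult(
        method="cars",
        selected=best["selected"],
        history=pd.DataFrame(rows),
        params={"n_runs": n_runs, "n_latent": k, "sample_ratio": sample_ratio, "n_cv": n_cv},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------


def spa(
    X: np.ndarray,
    y: np.ndarray,
    min_vars: int = 5,
    max_vars: int = 70,
    validation_fraction: float = 0.25,
    seed: int = 0,
    max_start_candidates: int = 64,
) -> SelectionResult:
    """Successive projections algorithm.

    For each candidate start column a chain is grown by repeatedly appending
    the column with the largest residual norm after projection onto the
    orthogonal complement of the chosen set; every chain prefix of length
    min_vars..max_vars is scored by validation RMSE of an ordinary linear
    regression.  With more columns than ``max_start_candidates`` an evenly
    spaced subset of starts is scanned to keep the search tractable.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_vars > min(n - 1, p):
        raise ValueError("max_vars must not exceed min(n-1, p)")
    if min_vars > max_vars:
        raise ValueError("min_vars must not exceed max_vars")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]

    if p <= max_start_candidates:
        starts = np.arange(p)
    else:
        starts = np.unique(np.linspace(0, p - 1, max_start_candidates).astype(int))

    def grow_chain(start: int) -> list[int]:
        R = Xt - Xt.mean(axis=0)  # residual matrix after projections
        chain = [start]
        norms0 = np.sum(R**2, axis=0)
        q = R[:, start].copy()
        nq = np.linalg.norm(q)
        if nq < 1e-12:
            return chain
        q /= nq
        R = R - np.outer(q, q @ R)
        while len(chain) < max_vars:
            norms = np.sum(R**2, axis=0)
            norms[chain] = -1.0
            j = int(np.argmax(norms))  # argmax takes the lowest index on ties
            if norms[j] <= 1e-12 * max(norms0[j], 1.0):
                break  # rank deficient: chain stops early
            chain.append(j)
            q = R[:, j].copy()
            q /= np.linalg.norm(q)
            R = R - np.outer(q, q @ R)
        return chain

    def score(cols: list[int]) -> float:
        design = np.column_stack([np.ones(len(train_idx)), Xt[:, cols]])
        beta, *_ = np.linalg.lstsq(design, yt, rcond=None)
        pred = beta[0] + Xv[:, cols] @ beta[1:]
        return float(np.sqrt(np.mean((yv - pred) ** 2)))

    best_cols, best_rmse = None, np.inf
    rows = []
    for start in starts:
        chain = grow_chain(int(start))
        for m in range(min_vars, min(max_vars, len(chain)) + 1):
            rmse = score(chain[:m])
            if rmse < best_rmse:
                best_cols, best_rmse = chain[:m], rmse
        rows.append({"iteration": int(start), "subset_size": len(chain), "rmsecv": score(chain[: max(min_vars, 1)])})
    if best_cols is None:
        raise ValueError("SPA found no chain of the requested length")
    return SelectionResult(
        method="spa",
        selected=np.array(best_cols),
        history=pd.DataFrame(rows),
        params={
            "min_vars": min_vars,
            "max_vars": max_vars,
            "validation_fraction": validation_fraction,
            "validation_rmse": best_rmse,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# IRIV
# ---------------------------------------------------------------------------


def iriv(
    X: np.ndarray,
    y: np.ndarray,
    n_rows_bms: int = 500,
    n_latent: int | None = None,
    n_cv: int = 5,
    alpha: float = 0.05,
    max_rounds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Iteratively retains informative variables.

    Each round draws a binary sampling matrix (inclusion probability 0.5),
    evaluates PLS RMSECV per row, and classifies each variable by
    DMEAN = mean(RMSECV | excluded) - mean(RMSECV | included) together with a
    two-sample t-test: DMEAN > 0 keeps the variable (strongly informative if
    significant), DMEAN <= 0 drops it.  Rounds repeat until nothing is
    dropped, then backward elimination removes single survivors whose
    removal lowers RMSECV.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 4:
        raise ValueError("IRIV needs at least 4 variables")
    if n_rows_bms < 50:
        raise ValueError("n_rows_bms must be >= 50")
    rng = np.random.default_rng(seed)
    k = _default_latent(X, y, n_latent, seed)
    support = np.arange(p)
    rows = []
    for rnd in range(1, max_rounds + 1):
        ps = support.size
        if ps <= 2:
            break
        B = rng.integers(0, 2, size=(n_rows_bms, ps)).astype(bool)
        # every row needs at least two variables for a PLS fit
        thin = B.sum(axis=1) < 2
        for r in np.flatnonzero(thin):
            B[r, rng.choice(ps, size=2, replace=False)] = True
        rmse = np.empty(n_rows_bms)
        for r in range(n_rows_bms):
            cols = support[B[r]]
            rmse[r] = _rmsecv(X[:, cols], y, k, n_cv, seed + rnd)
        keep = np.zeros(ps, dtype=bool)
        classes = np.empty(ps, dtype=object)
        for j in range(ps):
            inc, exc = rmse[B[:, j]], rmse[~B[:, j]]
            if inc.size < 2 or exc.size < 2:
                keep[j] = True
                classes[j] = "weak"
                continue
            dmean = float(exc.mean() - inc.mean())
            import warnings

            with warnings.catch_warnings():
                # near-identical RMSECVs trigger a harmless precision warning
                warnings.simplefilter("ignore", RuntimeWarning)
                pval = float(stats.ttest_ind(exc, inc, equal_var=False).pvalue)
            if not np.isfinite(pval):
                pval = 1.0
            if dmean > 0:
                keep[j] = True
                classes[j] = "strong" if pval < alpha else "weak"
            else:
                classes[j] = "interfering" if pval < alpha else "uninformative"
        rows.append(
            {
                "iteration": rnd,
                "subset_size": int(keep.sum()),
                "rmsecv": float(rmse.mean()),
                "n_strong": int(np.sum(classes == "strong")),
            }
        )
        if keep.all():
            break
        if not keep.any():
            raise ValueError(
                "IRIV dropped every variable; consider a smaller alpha or "
                "more informative data"
            )
        support = support[keep]

    # backward elimination of the survivors
    current = list(support)
    base = _rmsecv(X[:, current], y, k, n_cv, seed)
    improved = True
    while improved and len(current) > 2:
        improved = False
        scores = []
        for j in range(len(current)):
            trial = current[:j] + current[j + 1 :]
            scores.append(_rmsecv(X[:, trial], y, k, n_cv, seed))
        j_best = int(np.argmin(scores))
        if scores[j_best] < base:
            current.pop(j_best)
            base = scores[j_best]
            improved = True
    return SelectionResult(
        method="iriv",
        selected=np.array(current),
        history=pd.DataFrame(rows),
        params={
            "n_rows_bms": n_rows_bms,
            "n_latent": k,
            "n_cv": n_cv,
            "alpha": alpha,
            "max_rounds": max_rounds,
            "rmsecv": base,
        },
        seed=seed,
    )


def reduction_percent(n_selected: int, p: int) -> float:
    """Dimensionality reduction 100 * (1 - n_selected / p), rounded to 2 dp."""
    if not 0 < n_selected <= p:
        raise ValueError("need 0 < n_selected <= p")
    return round(100.0 * (1.0 - n_selected / p), 2)
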