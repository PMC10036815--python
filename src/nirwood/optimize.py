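"""Hyperparameter optimizers for the nonlinear calibration models.

* FOA (fruit-fly optimization): a 2-D swarm around a moving axis; each fly's
  candidate value is S = 1 / sqrt(X^2 + Y^2), guaranteeing positivity, which
  makes it a natural tuner for the GRNN spread.
* PSO (particle swarm): canonical velocity/position updates with position
  clamping, run in log10 coordinates of the SVR penalty C and RBF width g.
* Box-Behnken design + quadratic response surface (RSM): the 12 edge points
  with two coordinates at +-1 plus center replicates; a full second-order
  model of CVmse over the three PSO meta-parameters (cross-validation
  number, maximum generation, population size) is fitted and minimized over
  the coded cube, and the optimum is snapped to integer factor settings.

Both swarm optimizers are elitist: the best-so-far trace is non-increasing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import calibrate

__all__ = [
    "FOAConfig",
    "PSOConfig",
    "BBDesign",
    "foa_optimize",
    "foa_grnn_train",
    "pso_optimize",
    "pso_svm_train",
    "box_behnken_design",
    "fit_quadratic_surface",
    "rsm_optimize",
    "rsm_pso_svm_train",
    "DEFAULT_PSO_FACTORS",
]


@dataclass(frozen=True)
class FOAConfig:
    n_flies: int = 20
    n_iterations: int = 100
    init_axis_range: tuple[float, float] = (0.0, 1.0)
    step_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 2 or self.n_iterations < 1:
            raise ValueError("need n_flies >= 2 and n_iterations >= 1")
        if not all(np.isfinite(self.step_range)):
            raise ValueError("step_range must be finite")


@dataclass(frozen=True)
class PSOConfig:
    population: int = 40
    max_generation: int = 75
    n_cv: int = 10
    inertia: float = 0.8
    cognitive: float = 1.5
    social: float = 1.7
    C_range: tuple[float, float] = (2.0**-5, 2.0**10)
    g_range: tuple[float, float] = (2.0**-10, 2.0**5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2 or self.max_generation < 1:
            raise ValueError("need population >= 2 and max_generation >= 1")
        if self.n_cv < 2:
            raise ValueError("n_cv must be >= 2")
        if min(self.C_range) <= 0 or min(self.g_range) <= 0:
            raise ValueError("C and g search ranges must be positive")


# ---------------------------------------------------------------------------
# FOA
# ---------------------------------------------------------------------------


def foa_optimize(objective, config: FOAConfig) -> dict:
    """Minimize ``objective`` over positive scalars S = 1/distance.

    Each iteration perturbs the swarm axis per fly, evaluates the smell
    (objective) at S = 1/sqrt(X^2 + Y^2) and relocates the axis to the best
    fly; the best-so-far trace is non-increasing by elitism.
    """
    rng = np.random.default_rng(config.seed)
    axis = rng.uniform(*config.init_axis_range, size=2)
    best_value, best_score = None, np.inf
    trace = []
    for _ in range(config.n_iterations):
        steps = rng.uniform(*config.step_range, size=(config.n_flies, 2))
        pos = axis + steps
        dist = np.sqrt(np.sum(pos**2, axis=1))
        dist[dist < 1e-12] = 1e-12
        s = 1.0 / dist
        scores = np.array([objective(float(v)) for v in s])
        finite = np.isfinite(scores)
        if not finite.any():
            raise ValueError("objective returned no finite score in an iteration")
        i = int(np.flatnonzero(finite)[np.argmin(scores[finite])])
        if scores[i] < best_score:
            best_score = float(scores[i])
            best_value = float(s[i])
            axis = pos[i]
        trace.append(best_score)
    return {"best_value": best_value, "best_score": best_score, "trace": np.array(trace)}


def foa_grnn_train(
    X: np.ndarray,
    y: np.ndarray,
    foa_config: FOAConfig | None = None,
    n_cv: int = 5,
) -> tuple[calibrate.CalibrationModel, np.ndarray]:
    """Tune the GRNN spread by FOA against cross-validated MSE (CVmse)."""
    foa_config = foa_config or FOAConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()

    def objective(spread: float) -> float:
        res = calibrate.cross_validate(
            lambda A, b: calibrate.grnn_fit(A, b, spread),
            X, y, n_folds=n_cv, seed=foa_config.seed,
        )
        return res["cvmse"]

    result = foa_optimize(objective, foa_config)
    model = calibrate.grnn_fit(X, y, result["best_value"])
    model.hyperparameters["cvmse"] = result["best_score"]
    return model, result["trace"]


# ---------------------------------------------------------------------------
# PSO
# ---------------------------------------------------------------------------


def pso_optimize(objective_2d, config: PSOConfig, box: np.ndarray | None = None) -> dict:
    """Minimize a 2-D objective over a box with canonical PSO.

    ``box`` rows are (low, high) per coordinate; by default the log10 ranges
    of (C, g).  Positions are clamped to the box; the returned trace of
    global-best scores is non-increasing.
    """
    if box is None:
        box = np.log10(np.array([config.C_range, config.g_range]))
    box = np.asarray(box, dtype=float)
    lo, hi = box[:, 0], box[:, 1]
    if np.any(hi < lo):
        raise ValueError("box bounds reversed")
    if np.all(hi == lo):
        score = float(objective_2d(lo.copy()))
        return {"best_point": lo.copy(), "best_score": score, "trace": np.array([score])}
    rng = np.random.default_rng(config.seed)
    pos = rng.uniform(lo, hi, size=(config.population, 2))
    vel = rng.uniform(-(hi - lo), hi - lo, size=(config.population, 2)) * 0.1
    pbest = pos.copy()
    pbest_score = np.array([float(objective_2d(x)) for x in pos])
    g = int(np.argmin(pbest_score))
    gbest, gbest_score = pbest[g].copy(), float(pbest_score[g])
    trace = [gbest_score]
    for _ in range(config.max_generation):
        r1 = rng.uniform(size=(config.population, 2))
        r2 = rng.uniform(size=(config.population, 2))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest - pos)
        )
        pos = np.clip(pos + vel, lo, hi)
        scores = np.array([float(objective_2d(x)) for x in pos])
        better = scores < pbest_score
        pbest[better] = pos[better]
        pbest_score[better] = scores[better]
        g = int(np.argmin(pbest_score))
        if pbest_score[g] < gbest_score:
            gbest, gbest_score = pbest[g].copy(), float(pbest_score[g])
        trace.append(gbest_score)
    return {"best_point": gbest, "best_score": gbest_score, "trace": np.array(trace)}


def pso_svm_train(
    X: np.ndarray,
    y: np.ndarray,
    config: PSOConfig | None = None,
    epsilon: float = 0.01,
    fold_seed: int | None = None,
) -> tuple[calibrate.CalibrationModel, np.ndarray]:
    """Tune (C, g) of the RBF SVR by PSO; fitness is CVmse with n_cv folds.

    The conventional default point (C = 1, g = 1/p) is evaluated first and
    seeds the comparison, so the returned model is never worse than it.
    ``fold_seed`` decouples the CV fold assignment from the swarm seed so a
    caller can compare several PSO runs on identical folds.
    """
    config = config or PSOConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    fold_seed = config.seed if fold_seed is None else fold_seed

    def fitness(point: np.ndarray) -> float:
        C, g = 10.0 ** point[0], 10.0 ** point[1]
        res = calibrate.cross_validate(
            lambda A, b: calibrate.svr_fit(A, b, C, g, epsilon),
            X, y, n_folds=min(config.n_cv, y.size), seed=fold_seed,
        )
        return res["cvmse"]

    baseline_point = np.array([0.0, -np.log10(p)])
    baseline = fitness(baseline_point)
    result = pso_optimize(fitness, config)
    if baseline < result["best_score"]:
        result = {
            "best_point": baseline_point,
            "best_score": baseline,
            "trace": np.minimum(result["trace"], baseline),
        }
    C, g = 10.0 ** result["best_point"]
    model = calibrate.svr_fit(X, y, C, g, epsilon)
    model.hyperparameters["cvmse"] = result["best_score"]
    return model, result["trace"]


# ---------------------------------------------------------------------------
# Box-Behnken design and response surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BBDesign:
    """Three-factor Box-Behnken design with coded levels -1/0/+1."""

    factors: tuple[str, str, str]
    levels: dict  # name -> (low, mid, high) actual values
    runs: np.ndarray  # coded points, shape (12 + n_center, 3)
    n_center: int

    def actual(self, coded: np.ndarray) -> np.ndarray:
        """Affine coded -> actual mapping per factor."""
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        out = np.empty_like(coded)
        for j, name in enumerate(self.factors):
            low, mid, high = self.levels[name]
            half = (high - low) / 2.0
            out[:, j] = mid + coded[:, j] * half
        return out


def box_behnken_design(factor_levels: dict, n_center: int = 5) -> BBDesign:
    """Build the 12-edge-point + center Box-Behnken design.

    ``factor_levels`` maps exactly three factor names to their (low, mid,
    high) actual values.
    """
    if len(factor_levels) != 3:
        raise ValueError("Box-Behnken design here requires exactly 3 factors")
    for name, levels in factor_levels.items():
        if len(levels) != 3:
            raise ValueError(f"factor {name!r} must have exactly 3 levels")
        if not (levels[0] < levels[1] < levels[2]):
            raise ValueError(f"factor {name!r} levels must be increasing")
    edges = []
    for i, j in itertools.combinations(range(3), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            point = [0.0, 0.0, 0.0]
            point[i], point[j] = si, sj
            edges.append(point)
    runs = np.array(edges + [[0.0, 0.0, 0.0]] * n_center)
    return BBDesign(
        factors=tuple(factor_levels),
        levels=dict(factor_levels),
        runs=runs,
        n_center=n_center,
    )


_QUAD_TERMS = ("1", "x1", "x2", "x3", "x1:x2", "x1:x3", "x2:x3", "x1^2", "x2^2", "x3^2")


def _quad_design(points: np.ndarray) -> np.ndarray:
    x1, x2, x3 = points[:, 0], points[:, 1], points[:, 2]
    return np.column_stack(
        [np.ones(len(points)), x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1**2, x2**2, x3**2]
    )


def fit_quadratic_surface(design_points: np.ndarray, responses: np.ndarray) -> dict:
    """Least-squares full second-order surface over coded design points.

    Returns the coefficient mapping, R^2 and per-term t-test p-values.
    """
    points = np.atleast_2d(np.asarray(design_points, dtype=float))
    y = np.asarray(responses, dtype=float).ravel()
    if len(np.unique(points, axis=0)) < 10:
        raise ValueError("a full quadratic surface needs >= 10 distinct points")
    A = _quad_design(points)
    fit = sm.OLS(y, A).fit()
    coef = dict(zip(_QUAD_TERMS, fit.params))
    pvalues = dict(zip(_QUAD_TERMS, fit.pvalues))
    return {
        "coefficients": coef,
        "r2": float(fit.rsquared) if np.ptp(y) > 0 else 1.0,
        "pvalues": pvalues,
        "predict": lambda pts: _quad_design(np.atleast_2d(np.asarray(pts, float))) @ fit.params,
    }


def rsm_optimize(surface: dict, design: BBDesign, n_grid: int = 41) -> dict:
    """Minimize the fitted quadratic over the coded cube [-1, 1]^3.

    The minimizer is located on an n_grid^3 lattice, then each coordinate is
    snapped to the nearest feasible integer actual value (the three factors
    are integer-valued counts).
    """
    axis = np.linspace(-1.0, 1.0, n_grid)
    grid = np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T
    values = surface["predict"](grid)
    coded = grid[int(np.argmin(values))]
    actual = design.actual(coded)[0]
    snapped = np.array([int(round(v)) for v in actual])
    for j, name in enumerate(design.factors):
        low, _, high = design.levels[name]
        snapped[j] = int(np.clip(snapped[j], low, high))
    return {
        "coded": coded,
        "actual": dict(zip(design.factors, snapped.tolist())),
        "surface_value": float(np.min(values)),
    }


DEFAULT_PSO_FACTORS = {
    "n_cv": (5, 10, 15),
    "max_generation": (50, 75, 100),
    "population": (20, 40, 60),
}


def rsm_pso_svm_train(
    X: np.ndarray,
    y: np.ndarray,
    design: BBDesign | None = None,
    pso_base_config: PSOConfig | None = None,
    epsilon: float = 0.01,
) -> tuple[calibrate.CalibrationModel, dict]:
    """PSO-SVM with its meta-parameters tuned by Box-Behnken + RSM.

    Each design run executes a PSO-SVM training at that run's actual
    (n_cv, max_generation, population); the CVmse responses feed a quadratic
    surface whose constrained minimum fixes the final meta-parameters, and a
    last PSO-SVM training at the optimum yields the returned model.
    """
    design = design or box_behnken_design(DEFAULT_PSO_FACTORS)
    base = pso_base_config or PSOConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    records = []
    responses = []
    for r, coded in enumerate(design.runs):
        actual = design.actual(coded)[0]
        settings = {k: int(round(v)) for k, v in zip(design.factors, actual)}
        cfg = replace(
            base,
            n_cv=min(settings["n_cv"], y.size),
            max_generation=settings["max_generation"],
            population=settings["population"],
            seed=base.seed + r,
        )
        # swarm seed varies per run; fold assignment stays fixed so the
        # design responses are comparable experiments
        _, trace = pso_svm_train(X, y, cfg, epsilon, fold_seed=base.seed)
        cvmse = float(trace[-1])
        responses.append(cvmse)
        records.append({"run": r, **{f"coded_{f}": c for f, c in zip(design.factors, coded)},
                        **settings, "cvmse": cvmse})
    surface = fit_quadratic_surface(design.runs, np.array(responses))
    optimum = rsm_optimize(surface, design)
    cfg = replace(
        base,
        n_cv=min(int(optimum["actual"]["n_cv"]), y.size),
        max_generation=int(optimum["actual"]["max_generation"]),
        population=int(optimum["actual"]["population"]),
        seed=base.seed + len(design.runs),
    )
    model, trace = pso_svm_train(X, y, cfg, epsilon, fold_seed=base.seed)
    report = {
        "design_table": pd.DataFrame(records),
        "surface": surface,
        "optimum": optimum,
        "final_cvmse": float(trace[-1]),
        "trace": trace,
    }
    return model, report
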