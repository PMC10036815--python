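"""FOA, PSO, Box-Behnken design and the response-surface optimizer."""

import numpy as np
import pytest

from nirwood import calibrate
from nirwood.optimize import (
    DEFAULT_PSO_FACTORS,
    FOAConfig,
    PSOConfig,
    box_behnken_design,
    fit_quadratic_surface,
    foa_grnn_train,
    foa_optimize,
    pso_optimize,
    pso_svm_train,
    rsm_optimize,
    rsm_pso_svm_train,
)

TINY_FACTORS = {"n_cv": (3, 4, 5), "max_generation": (5, 10, 15), "population": (5, 10, 15)}


class TestFOA:
    def test_locates_scalar_minimum(self):
        result = foa_optimize(lambda s: (s - 0.3) ** 2, FOAConfig(n_flies=20, n_iterations=100, seed=9))
        assert abs(result["best_value"] - 0.3) < 0.05

    def test_trace_non_increasing_and_candidates_positive(self):
        seen = []

        def objective(s):
            seen.append(s)
            return abs(np.sin(7 * s)) + 0.1 * s

        result = foa_optimize(objective, FOAConfig(seed=2))
        assert (np.diff(result["trace"]) <= 0).all()
        assert all(s > 0 for s in seen)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FOAConfig(n_flies=1)
        with pytest.raises(ValueError):
            FOAConfig(step_range=(0.0, np.inf))


class TestFOAGRNN:
    def test_matches_grid_search_oracle(self):
        """The FOA-found spread lands within 20% of a 200-point grid scan."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 4))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=50)
        model, trace = foa_grnn_train(X, y, FOAConfig(seed=9), n_cv=5)
        spreads = np.linspace(0.05, 5.0, 200)
        cv = [
            calibrate.cross_validate(
                lambda A, b, s=s: calibrate.grnn_fit(A, b, s), X, y, 5, seed=9
            )["cvmse"]
            for s in spreads
        ]
        oracle = spreads[int(np.argmin(cv))]
        assert abs(model.hyperparameters["spread"] - oracle) / oracle < 0.20
        assert model.hyperparameters["cvmse"] <= min(cv) * 1.05
        assert (np.diff(trace) <= 0).all()

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] ** 2
        cfg = FOAConfig(n_iterations=20, seed=4)
        a, _ = foa_grnn_train(X, y, cfg, n_cv=4)
        b, _ = foa_grnn_train(X, y, cfg, n_cv=4)
        assert a.hyperparameters["spread"] == b.hyperparameters["spread"]


class TestPSO:
    def test_sphere(self):
        result = pso_optimize(
            lambda x: float(x @ x),
            PSOConfig(population=20, max_generation=100, seed=13),
            box=np.array([[-5.0, 5.0], [-5.0, 5.0]]),
        )
        assert np.linalg.norm(result["best_point"]) < 1e-2
        assert (np.diff(result["trace"]) <= 0).all()

    def test_particles_clamped_to_box(self):
        visited = []

        def objective(x):
            visited.append(x.copy())
            return float((x[0] - 10) ** 2 + x[1] ** 2)  # pulls toward the wall

        box = np.array([[-1.0, 1.0], [-1.0, 1.0]])
        pso_optimize(objective, PSOConfig(population=8, max_generation=20, seed=3), box=box)
        pts = np.array(visited)
        assert pts.min() >= -1.0 and pts.max() <= 1.0

    def test_degenerate_box(self):
        result = pso_optimize(lambda x: float(x @ x), PSOConfig(seed=0), box=np.array([[2.0, 2.0], [3.0, 3.0]]))
        np.testing.assert_array_equal(result["best_point"], [2.0, 3.0])


class TestPSOSVM:
    @pytest.fixture(scope="class")
    def data(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 5))
        y = np.tanh(X[:, 0]) + 0.5 * X[:, 1] + 0.05 * rng.normal(size=40)
        return X, y

    def test_beats_default_parameters(self, data):
        X, y = data
        cfg = PSOConfig(population=8, max_generation=10, n_cv=5, seed=13)
        model, trace = pso_svm_train(X, y, cfg)
        baseline = calibrate.cross_validate(
            lambda A, b: calibrate.svr_fit(A, b, 1.0, 1.0 / X.shape[1], 0.01),
            X, y, 5, seed=13,
        )["cvmse"]
        assert model.hyperparameters["cvmse"] <= baseline + 1e-12

    def test_near_log_grid_oracle(self, data):
        """PSO CVmse within 10% of a 20 x 20 log-grid scan."""
        X, y = data
        cfg = PSOConfig(population=10, max_generation=15, n_cv=5, seed=13)
        model, _ = pso_svm_train(X, y, cfg)
        best = np.inf
        for lc in np.linspace(np.log10(cfg.C_range[0]), np.log10(cfg.C_range[1]), 20):
            for lg in np.linspace(np.log10(cfg.g_range[0]), np.log10(cfg.g_range[1]), 20):
                cv = calibrate.cross_validate(
                    lambda A, b: calibrate.svr_fit(A, b, 10**lc, 10**lg, 0.01),
                    X, y, 5, seed=13,
                )["cvmse"]
                best = min(best, cv)
        assert model.hyperparameters["cvmse"] <= best * 1.10

    def test_deterministic(self, data):
        X, y = data
        cfg = PSOConfig(population=6, max_generation=5, n_cv=4, seed=21)
        a, _ = pso_svm_train(X, y, cfg)
        b, _ = pso_svm_train(X, y, cfg)
        assert a.hyperparameters["C"] == b.hyperparameters["C"]
        assert a.hyperparameters["g"] == b.hyperparameters["g"]


class TestBoxBehnken:
    def test_edge_points_and_centers(self):
        design = box_behnken_design(DEFAULT_PSO_FACTORS, n_center=5)
        assert design.runs.shape == (17, 3)
        edges = design.runs[:12]
        # exactly the 12 points with two coordinates +-1 and one 0
        assert all(sorted(np.abs(r)) == [0.0, 1.0, 1.0] for r in edges)
        assert len({tuple(r) for r in edges}) == 12
        assert (design.runs[12:] == 0).all()

    def test_coded_to_actual_mapping(self):
        design = box_behnken_design(DEFAULT_PSO_FACTORS)
        np.testing.assert_array_equal(design.actual(np.array([-1, -1, -1]))[0], [5, 50, 20])
        np.testing.assert_array_equal(design.actual(np.array([0, 0, 0]))[0], [10, 75, 40])
        np.testing.assert_array_equal(design.actual(np.array([1, 1, 1]))[0], [15, 100, 60])

    def test_linear_columns_orthogonal(self):
        design = box_behnken_design(DEFAULT_PSO_FACTORS)
        r = design.runs
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.sum(r[:, i] * r[:, j]) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            box_behnken_design({"a": (1, 2, 3), "b": (1, 2, 3)})
        with pytest.raises(ValueError):
            box_behnken_design({"a": (1, 2, 3), "b": (1, 2, 3), "c": (3, 2, 1)})


class TestQuadraticSurface:
    def test_exact_recovery_of_quadratic_truth(self):
        design = box_behnken_design(DEFAULT_PSO_FACTORS)
        r = design.runs
        y = 1.0 + 2.0 * r[:, 0] + 3.0 * r[:, 2] ** 2
        surface = fit_quadratic_surface(r, y)
        assert surface["coefficients"]["x1"] == pytest.approx(2.0, abs=1e-8)
        assert surface["coefficients"]["x3^2"] == pytest.approx(3.0, abs=1e-8)
        assert abs(surface["coefficients"]["x1:x2"]) < 1e-8

    def test_constant_responses(self):
        design = box_behnken_design(DEFAULT_PSO_FACTORS)
        surface = fit_quadratic_surface(design.runs, np.full(17, 2.5))
        for term, value in surface["coefficients"].items():
            if term != "1":
                assert abs(value) < 1e-10

    def test_noise_rarely_flagged_significant(self):
        """Pure-noise responses: no term significant at alpha = 0.01 in >=
        90% of 50 seeds."""
        design = box_behnken_design(DEFAULT_PSO_FACTORS)
        clean = 0
        for seed in range(50):
            y = np.random.default_rng(seed).normal(size=17)
            surface = fit_quadratic_surface(design.runs, y)
            pvals = [p for t, p in surface["pvalues"].items() if t != "1"]
            clean += all(p >= 0.01 for p in pvals)
        assert clean >= 45


class TestRSMOptimize:
    def test_center_minimum_maps_to_10_75_40(self):
        design = box_behnken_design(DEFAULT_PSO_FACTORS)
        r = design.runs
        surface = fit_quadratic_surface(r, 1 + r[:, 0] ** 2 + r[:, 1] ** 2 + r[:, 2] ** 2)
        optimum = rsm_optimize(surface, design)
        assert optimum["actual"] == {"n_cv": 10, "max_generation": 75, "population": 40}
        np.testing.assert_allclose(optimum["coded"], [0, 0, 0], atol=1e-12)

    def test_monotone_surface_maps_to_5_50_20(self):
        design = box_behnken_design(DEFAULT_PSO_FACTORS)
        r = design.runs
        surface = fit_quadratic_surface(r, 1 + r[:, 0] + r[:, 1] + r[:, 2])
        assert rsm_optimize(surface, design)["actual"] == {
            "n_cv": 5,
            "max_generation": 50,
            "population": 20,
        }


class TestRSMPSOSVM:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 4))
        y = np.tanh(X[:, 0]) + 0.05 * rng.normal(size=30)
        design = box_behnken_design(TINY_FACTORS, n_center=5)
        base = PSOConfig(population=10, max_generation=10, n_cv=4, seed=13)
        return rsm_pso_svm_train(X, y, design, base), (X, y, design, base)

    def test_one_cvmse_per_design_run(self, trained):
        (model, report), _ = trained
        assert len(report["design_table"]) == 17

    def test_final_cvmse_not_worse_than_median_run(self, trained):
        (model, report), _ = trained
        assert report["final_cvmse"] <= report["design_table"]["cvmse"].median()

    def test_deterministic(self, trained):
        (model, report), (X, y, design, base) = trained
        model2, report2 = rsm_pso_svm_train(X, y, design, base)
        assert model2.hyperparameters["C"] == model.hyperparameters["C"]
        assert report2["final_cvmse"] == report["final_cvmse"]
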