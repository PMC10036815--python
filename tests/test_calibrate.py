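"""Calibration models: linear baselines, GRNN, SVR, cross-validation."""

import numpy as np
import pytest

from nirwood.calibrate import (
    cross_validate,
    grnn_fit,
    grnn_predict,
    pcr_fit,
    pls_fit,
    select_n_latent,
    svr_fit,
)
from nirwood.core import average_replicates, to_absorbance
from nirwood.synthgen import SynthConfig, generate_dataset
from tests.conftest import P256


def _ols_predict(X, y, Q):
    design = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[0] + Q @ beta[1:]


class TestLinearModels:
    def test_univariate_pls_is_least_squares_line(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 1))
        y = 3.0 * x[:, 0] + 0.5 + 0.1 * rng.normal(size=12)
        model = pls_fit(x, y, 1)
        np.testing.assert_allclose(model.predict(x), _ols_predict(x, y, x), atol=1e-8)

    @pytest.mark.parametrize("fitter", [pls_fit, pcr_fit])
    def test_full_rank_equals_ols_oracle(self, fitter):
        """With as many components as the rank, both factor models collapse
        onto ordinary least squares (10 x 4 random design)."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fitter(X, y, 4)
        np.testing.assert_allclose(model.predict(X), _ols_predict(X, y, X), atol=1e-8)

    def test_pls_beats_pcr_on_training_rmse(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 20))
        y = X @ rng.normal(size=20) + 0.1 * rng.normal(size=40)
        for k in (1, 2, 3):
            rmse_pls = np.sqrt(np.mean((y - pls_fit(X, y, k).predict(X)) ** 2))
            rmse_pcr = np.sqrt(np.mean((y - pcr_fit(X, y, k).predict(X)) ** 2))
            assert rmse_pls <= rmse_pcr + 1e-12

    def test_isotropic_first_component_share(self):
        """On isotropic data the leading principal component carries ~1/p of
        the variance."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 10))
        ratio = PCA(n_components=1).fit(X).explained_variance_ratio_[0]
        assert ratio == pytest.approx(0.1, abs=0.02)

    def test_noise_free_linear_density_is_solvable(self):
        """nonlinearity 0, noise 0: PLS attains R2 > 0.999 on training."""
        cfg = SynthConfig(
            n_samples=40,
            nonlinearity_strength=0.0,
            noise_sd=0.0,
            baseline_amplitude=0.0,
            scatter_slope_range=(1, 1),
            scatter_offset_range=(0, 0),
            seed=1,
            **P256,
        )
        ds, _ = generate_dataset(cfg)
        ab = to_absorbance(average_replicates(ds, 3))
        model = pls_fit(ab.spectra, ab.density, 5)
        pred = model.predict(ab.spectra)
        ss = 1 - np.sum((ab.density - pred) ** 2) / np.sum((ab.density - ab.density.mean()) ** 2)
        assert ss > 0.999

    def test_invalid_component_counts(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = X[:, 0]
        with pytest.raises(ValueError):
            pls_fit(X, y, 0)
        with pytest.raises(ValueError):
            pls_fit(X, y, 6)
        with pytest.raises(ValueError, match="constant"):
            pls_fit(X, np.ones(6), 1)


class TestGRNN:
    def test_equidistant_query_averages(self):
        train = np.array([[0.0], [2.0]])
        target = np.array([0.0, 1.0])
        for spread in (0.1, 1.0, 10.0):
            assert grnn_predict(train, target, [[1.0]], spread)[0] == pytest.approx(0.5)

    def test_small_spread_interpolates(self):
        train = np.array([[0.0], [1.0], [2.0]])
        target = np.array([5.0, -1.0, 3.0])
        out = grnn_predict(train, target, train, spread=1e-3)
        np.testing.assert_allclose(out, target, atol=1e-9)

    def test_large_spread_gives_global_mean(self):
        rng = np.random.default_rng(1)
        train = rng.normal(size=(20, 3))
        target = rng.normal(size=20)
        out = grnn_predict(train, target, rng.normal(size=(5, 3)), spread=1e6)
        np.testing.assert_allclose(out, target.mean(), atol=1e-6)

    def test_constant_targets_reproduced(self):
        """Kernel weights sum to one, so constants pass through exactly."""
        rng = np.random.default_rng(1)
        train = rng.normal(size=(10, 2))
        out = grnn_predict(train, np.full(10, 0.8), rng.normal(size=(4, 2)), 0.5)
        np.testing.assert_allclose(out, 0.8, atol=1e-12)

    def test_spread_must_be_positive(self):
        with pytest.raises(ValueError):
            grnn_predict(np.ones((2, 1)), np.ones(2), np.ones((1, 1)), 0.0)


class TestSVR:
    def test_epsilon_tube_absorbs_near_constant_targets(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = 1.0 + 1e-4 * rng.normal(size=20)
        model = svr_fit(X, y, C=1.0, g=0.1, epsilon=0.5)
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=0.01)

    def test_exact_fit_of_line(self):
        x = np.linspace(0, 1, 5)[:, None]
        y = x[:, 0]
        model = svr_fit(x, y, C=1e4, g=1.0, epsilon=1e-4)
        rmse = np.sqrt(np.mean((model.predict(x) - y) ** 2))
        assert rmse < 1e-3

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        perm = rng.permutation(30)
        a = svr_fit(X, y, C=10, g=0.5)
        b = svr_fit(X[perm], y[perm], C=10, g=0.5)
        Q = rng.normal(size=(6, 3))
        # the SMO solver is iterative, so invariance holds to its tolerance
        np.testing.assert_allclose(a.predict(Q), b.predict(Q), atol=1e-6)

    def test_parameter_validation(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            svr_fit(X, X[:, 0], C=0, g=1)
        with pytest.raises(ValueError):
            svr_fit(X, X[:, 0], C=1, g=-1)


class TestCrossValidation:
    def test_leave_one_out_boundary(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        y = X[:, 0]
        res = cross_validate(lambda A, b: pls_fit(A, b, 2), X, y, n_folds=12, seed=0)
        assert len(res["fold_mse"]) == 12

    def test_perfect_model_zero_cvmse(self):
        X = np.linspace(0, 1, 20)[:, None]
        y = 2 * X[:, 0] + 0.3

        class Exact:
            def predict(self, Q):
                return 2 * Q[:, 0] + 0.3

        res = cross_validate(lambda A, b: Exact(), X, y, n_folds=4, seed=1)
        assert res["cvmse"] == pytest.approx(0.0, abs=1e-20)

    def test_row_order_invariance_with_keys(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 4))
        y = X[:, 1] + 0.1 * rng.normal(size=24)
        keys = np.array([f"s{i}" for i in range(24)])
        perm = rng.permutation(24)
        a = cross_validate(lambda A, b: pls_fit(A, b, 2), X, y, 4, seed=3, keys=keys)
        b = cross_validate(
            lambda A, b: pls_fit(A, b, 2), X[perm], y[perm], 4, seed=3, keys=keys[perm]
        )
        assert a["cvmse"] == pytest.approx(b["cvmse"], rel=1e-12)

    def test_fold_bounds(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            cross_validate(lambda A, b: None, X, np.arange(5.0), n_folds=1)

    def test_select_n_latent_reasonable(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 15))
        y = X[:, :3] @ np.array([1.0, -2.0, 1.5]) + 0.05 * rng.normal(size=40)
        k = select_n_latent(X, y, max_latent=10, seed=7)
        assert 2 <= k <= 10  # must not collapse to a single component


class TestNoLeakage:
    @pytest.mark.parametrize(
        "fitter",
        [
            lambda X, y: pls_fit(X, y, 3),
            lambda X, y: pcr_fit(X, y, 3),
            lambda X, y: grnn_fit(X, y, 1.0),
            lambda X, y: svr_fit(X, y, 10.0, 0.1),
        ],
        ids=["pls", "pcr", "grnn", "svr"],
    )
    def test_predictions_independent_of_query_batch(self, fitter):
        """Centering/scaling is frozen at fit time: a query's prediction
        cannot change when other (wildly different) queries join the batch."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 5))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        model = fitter(X, y)
        q = rng.normal(size=(1, 5))
        alone = model.predict(q)
        batch = np.vstack([q, 100.0 + 50.0 * rng.normal(size=(10, 5))])
        together = model.predict(batch)[:1]
        np.testing.assert_allclose(alone, together, atol=1e-10)
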