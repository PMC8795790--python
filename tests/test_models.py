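"""The four regressors: fit contracts, selection protocols, oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import pqsar
from pqsar import ConfigError, RegressorConfig, predict
from pqsar.models import (fit, fit_gp, fit_pls, fit_rf, fit_svr, pin_config,
                          scaling_for)


def linear_data(seed, n=60, p=5, noise=0.3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    return X, X @ beta + noise * rng.normal(size=n)


class TestPLS:
    def test_single_column_signal_selects_one_component(self):
        rng = np.random.default_rng(0)
        # orthonormal design: the single latent direction is exact
        X, _ = np.linalg.qr(rng.normal(size=(300, 6)))
        y = X[:, 0].copy()
        m = fit_pls(X, y, RegressorConfig(method="pls", seed=0))
        assert m.params["nlv"] == 1
        assert m.q2_trace[0] >= 0.99

    def test_full_rank_nlv_equals_ols(self):
        for seed in range(20):
            X, y = linear_data(seed, n=50, p=5)
            m = fit_pls(X, y, RegressorConfig(method="pls", pls_fixed_nlv=5))
            A = np.column_stack([np.ones(len(y)), X])
            ols = A @ np.linalg.solve(A.T @ A, A.T @ y)
            assert np.max(np.abs(predict(m, X) - ols)) < 1e-8

    def test_pure_noise_keeps_model_small(self):
        nlvs, q2s = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = rng.normal(size=(100, 10)), rng.normal(size=100)
            m = fit_pls(X, y, RegressorConfig(method="pls", seed=seed))
            nlvs.append(m.params["nlv"])
            q2s.append(max(m.q2_trace[:max(m.params["nlv"], 1)]))
        assert np.median(nlvs) <= 1
        assert np.median(q2s) <= 0.1

    def test_matches_sklearn_pls_at_fixed_nlv(self):
        from sklearn.cross_decomposition import PLSRegression
        X, y = linear_data(3, n=40, p=6)
        m = fit_pls(X, y, RegressorConfig(method="pls", pls_fixed_nlv=3))
        sk = PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(predict(m, X), sk.predict(X).ravel(),
                                   atol=1e-8)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="non-constant"):
            fit_pls(X, np.ones(20), RegressorConfig(method="pls"))

    def test_selection_trace_covers_candidates(self):
        X, y = linear_data(1, n=50, p=4)
        m = fit_pls(X, y, RegressorConfig(method="pls", seed=1))
        assert len(m.q2_trace) == min(4, 50 - 1)


class TestSVR:
    def test_wide_tube_gives_flat_model(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        eps = (y.max() - y.min()) / 2 + 1e-6
        m = fit_svr(X, y, RegressorConfig(
            method="svr", svr_epsilon=(eps,), svr_C=(1.0,), svr_sigma2=(1.0,)))
        pred = predict(m, X)
        assert np.all(np.abs(pred - y) <= eps + 1e-9)
        assert np.ptp(pred) < 1e-9  # flat: the tube covers every target

    def test_near_interpolation_limit(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(8, 2)), rng.normal(size=8)
        m = fit_svr(X, y, RegressorConfig(
            method="svr", svr_epsilon=(0.0,), svr_C=(1e6,), svr_sigma2=(0.01,)))
        assert np.max(np.abs(predict(m, X) - y)) < 1e-3

    def test_selected_triple_minimizes_trace(self):
        X, y = linear_data(2, n=40, p=3)
        m = fit_svr(X, y, RegressorConfig(
            method="svr", seed=2, cv_folds=4,
            svr_epsilon=(0.05, 0.2), svr_C=(1.0, 10.0),
            svr_sigma2_factors=(1.0, 4.0)))
        best = min(t["rmse_cv"] for t in m.trace)
        selected = next(t for t in m.trace
                        if (t["epsilon"], t["C"], t["sigma2"]) ==
                        (m.params["epsilon"], m.params["C"], m.params["sigma2"]))
        assert selected["rmse_cv"] == best

    def test_empty_grid_rejected(self):
        X, y = linear_data(0, n=20, p=2)
        with pytest.raises(ConfigError, match="empty"):
            fit_svr(X, y, RegressorConfig(method="svr", svr_epsilon=()))


class TestRF:
    def test_seed_determinism(self):
        X, y = linear_data(0, n=80, p=4)
        cfg = RegressorConfig(method="rf", seed=5, cv_folds=3,
                              rf_ntree=(50,), rf_mtry=(2,))
        m1, m2 = fit_rf(X, y, cfg), fit_rf(X, y, cfg)
        np.testing.assert_array_equal(predict(m1, X), predict(m2, X))

    def test_constant_response(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        m = fit_rf(X, np.full(30, 2.5), RegressorConfig(
            method="rf", rf_ntree=(50,), rf_mtry=(1,)))
        np.testing.assert_allclose(predict(m, X), 2.5)

    def test_binary_feature_oob_recovery(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 2, size=(500, 1)).astype(float)
            y = X[:, 0].copy()
            m = fit_rf(X, y, RegressorConfig(
                method="rf", seed=seed, rf_ntree=(300,), rf_mtry=(1,)))
            errs.append(m.extras["oob_rmse"])
        assert max(errs) <= 0.05

    def test_bad_mtry_rejected(self):
        X, y = linear_data(0, n=20, p=3)
        with pytest.raises(ConfigError, match="mtry"):
            fit_rf(X, y, RegressorConfig(method="rf", rf_mtry=(10,)))


class TestGP:
    def test_fixed_theta_matches_dense_solve(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
        sv, ls, nv = 1.5, 2.0, 0.1
        m = fit_gp(X, y, RegressorConfig(method="gp",
                                         gp_fixed_theta=(sv, ls, nv)))
        Xs = rng.normal(size=(7, 3))
        K = sv * np.exp(-cdist(X, X, "sqeuclidean") / (2 * ls ** 2)) \
            + nv * np.eye(20)
        Ks = sv * np.exp(-cdist(Xs, X, "sqeuclidean") / (2 * ls ** 2))
        direct = Ks @ np.linalg.solve(K, y)
        assert np.max(np.abs(predict(m, Xs) - direct)) < 1e-8

    def test_interpolation_limit(self):
        rng = np.random.default_rng(1)
        # well-separated points keep the near-noiseless kernel well conditioned
        X, y = rng.uniform(-5, 5, size=(10, 2)), rng.normal(size=10)
        m = fit_gp(X, y, RegressorConfig(method="gp",
                                         gp_fixed_theta=(1.0, 1.0, 1e-10)))
        assert np.max(np.abs(predict(m, X) - y)) < 1e-6

    def test_optimized_lml_beats_every_start(self):
        X, y = linear_data(2, n=40, p=3)
        m = fit_gp(X, y, RegressorConfig(method="gp", seed=2, gp_restarts=3))
        assert all(m.extras["lml"] >= t["lml_init"] - 1e-9 for t in m.trace)

    def test_predictive_variance_nonnegative(self):
        X, y = linear_data(3, n=30, p=2)
        m = fit_gp(X, y, RegressorConfig(method="gp", seed=3, gp_restarts=2))
        _, std = predict(m, np.random.default_rng(0).normal(size=(15, 2)),
                         return_std=True)
        assert np.all(std >= 0)

    def test_size_guard(self):
        with pytest.raises(ValueError, match="guard"):
            fit_gp(np.zeros((10_001, 1)), np.zeros(10_001),
                   RegressorConfig(method="gp"))


@pytest.fixture(scope="module")
def fitted():
    X, y = linear_data(0, n=50, p=4)
    return X, y, fit_pls(X, y, RegressorConfig(method="pls", seed=0))


class TestPredictContract:
    def test_column_mismatch(self, fitted):
        X, y, m = fitted
        with pytest.raises(ValueError, match="columns"):
            predict(m, X[:, :2])

    def test_empty_input(self, fitted):
        _, _, m = fitted
        assert predict(m, np.empty((0, 4))).shape == (0,)

    def test_row_permutation_equivariance(self, fitted):
        X, _, m = fitted
        perm = np.random.default_rng(1).permutation(len(X))
        np.testing.assert_allclose(predict(m, X)[perm], predict(m, X[perm]))


class TestConfigAndSerialization:
    def test_default_scaling_per_method(self):
        assert scaling_for(RegressorConfig(method="pls")) == "autoscale"
        assert scaling_for(RegressorConfig(method="svr")) == "range_pm1"
        assert scaling_for(RegressorConfig(method="rf")) == "range_pm1"
        assert scaling_for(RegressorConfig(method="gp")) == "autoscale"
        assert scaling_for(RegressorConfig(method="rf",
                                           scaling="autoscale")) == "autoscale"

    def test_unknown_method_and_bad_threshold(self):
        with pytest.raises(ConfigError):
            RegressorConfig(method="mlp")
        with pytest.raises(ConfigError):
            RegressorConfig(method="pls", pls_q2_threshold=0.0)

    @pytest.mark.parametrize("method,kw", [
        ("pls", {}),
        ("svr", {"svr_epsilon": (0.1,), "svr_C": (1.0,), "svr_sigma2": (1.0,)}),
        ("rf", {"rf_ntree": (30,), "rf_mtry": (2,)}),
        ("gp", {"gp_restarts": 2}),
    ])
    def test_pin_and_serialization_roundtrip(self, method, kw, tmp_path):
        X, y = linear_data(1, n=40, p=4)
        cfg = RegressorConfig(method=method, seed=1, cv_folds=4, **kw)
        m = fit(X, y, cfg)
        pinned = pin_config(cfg, m)
        m2 = fit(X, y, pinned)
        assert m2.params == m.params

        path = tmp_path / "model.joblib"
        pqsar.save_model(m, path)
        loaded = pqsar.load_model(path)
        np.testing.assert_array_equal(predict(loaded, X), predict(m, X))
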