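import numpy as np
import pytest
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression as SkPLS

from oilspec.exceptions import DegenerateInputError, OilspecError
from oilspec.pls import (
    PLS1Regression,
    PLS1RegressionCV,
    fit_pls1,
    load_model,
    loocv_select,
    r_squared,
    rmse,
    save_model,
)


def _naive_grouped_cv(X, y, groups, k_max):
    """Reference grouped LOO using the primal NIPALS fit (oracle)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    garr = np.asarray(groups)
    uniq = list(dict.fromkeys(garr.tolist()))
    k_cap = min(k_max, len(uniq) - 2, X.shape[1])
    sq = np.zeros(k_cap)
    for g in uniq:
        tr = garr != g
        te = ~tr
        for k in range(1, k_cap + 1):
            m = PLS1Regression(n_components=k).fit(X[tr], y[tr])
            sq[k - 1] += np.sum((y[te] - m.predict(X[te])) ** 2)
    return np.sqrt(sq / len(y))


class TestPLS1Fit:
    def test_univariate_equals_simple_regression(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = 2.5 * x + 1.0 + 0.1 * rng.normal(size=15)
        m = fit_pls1(x[:, None], y, k=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert np.isclose(m.coef_[0], slope, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_matches_pseudoinverse(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        m = fit_pls1(X, y, k=4)
        Xc = X - X.mean(axis=0)
        b_ls = np.linalg.pinv(Xc) @ (y - y.mean())
        pred_ls = Xc @ b_ls + y.mean()
        assert np.allclose(m.predict(X), pred_ls, rtol=1e-8, atol=1e-8)

    def test_constant_y_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_pls1(np.random.default_rng(0).normal(size=(6, 3)), np.ones(6), 1)

    def test_mean_row_predicts_y_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        m = fit_pls1(X, y, k=3)
        pred = m.predict(np.tile(X.mean(axis=0), (4, 1)))
        assert np.allclose(pred, y.mean(), atol=1e-10)

    def test_exact_recovery_of_linear_map(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        a = rng.normal(size=6)
        y = X @ a + 3.0
        m = fit_pls1(X, y, k=6)
        assert np.allclose(m.predict(X), y, atol=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        m1 = fit_pls1(X, y, k=4)
        m2 = fit_pls1(X, 10.0 * y, k=4)
        assert np.allclose(m2.coef_, 10.0 * m1.coef_, rtol=1e-8)
        assert np.isclose(
            rmse(10 * y, m2.predict(X)), 10 * rmse(y, m1.predict(X)), rtol=1e-8
        )

    def test_rmsec_non_increasing_in_factors(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        errs = [rmse(y, fit_pls1(X, y, k=k).predict(X)) for k in range(1, 10)]
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_pls(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(14, 9))
        y = X @ rng.normal(size=9) + 0.3 * rng.normal(size=14)
        for k in (1, 3, 5):
            ours = fit_pls1(X, y, k=k).predict(X)
            sk = SkPLS(n_components=k, scale=False).fit(X, y[:, None]).predict(X).ravel()
            assert np.allclose(ours, sk, atol=1e-8)

    def test_invalid_factor_count(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(OilspecError):
            fit_pls1(X, np.arange(5.0), k=5)

    def test_predict_column_mismatch(self):
        m = fit_pls1(np.random.default_rng(0).normal(size=(6, 3)), np.arange(6.0), 2)
        with pytest.raises(OilspecError, match="column"):
            m.predict(np.ones((2, 4)))

    def test_sklearn_protocol(self):
        est = PLS1Regression(n_components=3)
        assert clone(est).get_params()["n_components"] == 3


class TestMetrics:
    def test_r_squared_cases(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, y) == 1.0
        assert np.isclose(r_squared(y, np.full(4, y.mean())), 0.0)
        assert r_squared(y, -y) < 0.0  # worse than the mean predictor

    def test_rmse_cases(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert np.isclose(rmse([1.0, -1.0], [0.0, 0.0]), 1.0)
        assert np.isclose(rmse([3.0], [0.0]), 3.0)

    def test_constant_y_rejected(self):
        with pytest.raises(DegenerateInputError):
            r_squared([2.0, 2.0], [1.0, 3.0])


class TestLoocv:
    @pytest.mark.parametrize("seed", range(6))
    def test_gram_cv_matches_primal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(18, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=18)
        groups = list(np.repeat(np.arange(6), 3))
        cv = loocv_select(X, y, groups=groups, k_max=4)
        ref = _naive_grouped_cv(X, y, groups, 4)
        assert np.allclose(cv.rmsecv_by_k, ref, rtol=1e-9, atol=1e-9)

    def test_ungrouped_matches_row_loo(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        cv = loocv_select(X, y, k_max=3)
        ref = _naive_grouped_cv(X, y, np.arange(10), 3)
        assert np.allclose(cv.rmsecv_by_k, ref, rtol=1e-9)

    def test_perfect_univariate_signal(self):
        # only column 2 carries information; the rest are constant, so one
        # latent factor suffices and the smallest-k tie-break fires
        rng = np.random.default_rng(5)
        X = np.ones((12, 5))
        X[:, 2] = rng.normal(size=12)
        y = 4.0 * X[:, 2]
        cv = loocv_select(X, y, k_max=5)
        assert cv.best_k == 1
        assert cv.rmsecv_by_k[0] < 1e-8 * np.std(y)

    def test_replicate_grouping_prevents_leakage(self):
        rng = np.random.default_rng(6)
        n, q = 10, 8
        X = rng.normal(size=(n, q))
        y = X @ rng.normal(size=q) + 0.5 * rng.normal(size=n)
        X3 = np.repeat(X, 3, axis=0)
        y3 = np.repeat(y, 3)
        groups = np.repeat(np.arange(n), 3)
        grouped = loocv_select(X3, y3, groups=groups, k_max=5)
        leaky = loocv_select(X3, y3, groups=None, k_max=5)
        base = loocv_select(X, y, k_max=5)
        # grouped CV on replicated rows equals leave-one-sample-out ...
        assert np.allclose(grouped.rmsecv_by_k, base.rmsecv_by_k[: len(grouped.rmsecv_by_k)], rtol=1e-9)
        # ... while row-wise LOO sees the replicate copies and looks better
        assert leaky.rmsecv_by_k.min() < grouped.rmsecv_by_k.min()

    def test_pure_noise_cv_error_near_response_sd(self):
        # over repeated draws the best cross-validated error cannot fall far
        # below the response spread: there is nothing to learn
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(20):
            X = rng.normal(size=(12, 6))
            y = rng.normal(size=12)
            cv = loocv_select(X, y, k_max=8)
            ratios.append(cv.rmsecv_by_k.min() / np.std(y, ddof=1))
        assert np.median(ratios) >= 0.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(OilspecError):
            loocv_select(np.ones((2, 3)), np.array([1.0, 2.0]), k_max=2)


class TestPLS1RegressionCV:
    def test_fit_selects_and_refits(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 10))
        y = X[:, 0] - 2 * X[:, 3] + 0.05 * rng.normal(size=15)
        est = PLS1RegressionCV(max_components=6).fit(X, y)
        assert 1 <= est.best_k_ <= 6
        assert est.rmsecv_.size == min(6, 13, 10)
        assert r_squared(y, est.predict(X)) > 0.95

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        m = fit_pls1(X, y, k=3)
        save_model(m, tmp_path / "model.txt")
        back = load_model(tmp_path / "model.txt")
        assert np.allclose(back.predict(X), m.predict(X), atol=0, rtol=0)
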