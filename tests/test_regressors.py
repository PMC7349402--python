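"""Regressor fits, rankings and closed-form oracles."""

import numpy as np
import pytest

from morphage.regressors import (RegressorSpec, expected_oob_fraction,
                                 fit_lasso_inner_cv, fit_predict_linear_svr,
                                 fit_random_forest, rank_svm_rfe,
                                 rf_permutation_importance)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


def svr_spec(**kw):
    return RegressorSpec(family="linear_svr", **kw)


def lasso_spec(grid, **kw):
    return RegressorSpec(family="l1_linear", lambda_grid=tuple(grid), **kw)


class TestLinearSVR:
    def test_realizable_function_within_epsilon(self):
        x = np.linspace(0, 10, 30).reshape(-1, 1)
        y = 3 * x[:, 0] + 2
        pred = fit_predict_linear_svr(x, y, x, svr_spec())
        assert np.abs(pred - y).mean() <= 0.1 + 1e-6

    def test_column_order_invariance(self, rng):
        x = rng.normal(size=(80, 6))
        y = x @ np.array([1.0, -2, 0, 0.5, 0, 0]) + 0.1 * rng.normal(size=80)
        perm = [3, 0, 5, 1, 4, 2]
        p1 = fit_predict_linear_svr(x, y, x, svr_spec())
        p2 = fit_predict_linear_svr(x[:, perm], y, x[:, perm], svr_spec())
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_duplicated_column_stays_in_tube(self):
        # duplicating a feature halves its effective penalty, so the exact
        # solution moves; on a realizable problem predictions must still
        # track the target within the epsilon tube
        x = np.linspace(0, 10, 30).reshape(-1, 1)
        y = 3 * x[:, 0] + 2
        xd = np.hstack([x, x])
        pred = fit_predict_linear_svr(xd, y, xd, svr_spec())
        assert np.abs(pred - y).max() <= 0.1 + 1e-3

    def test_constant_target_rejected(self):
        x = np.ones((10, 2))
        with pytest.raises(ValueError):
            fit_predict_linear_svr(x, np.ones(10), x, svr_spec())


class TestSvmRfe:
    def test_planted_feature_ranked_first(self, rng):
        x = rng.normal(size=(200, 51))
        y = x[:, 7].copy()
        ranking = rank_svm_rfe(x, y, svr_spec())
        assert ranking.order[0] == 7

    def test_ranking_is_full_permutation(self, rng):
        x = rng.normal(size=(40, 23))
        y = rng.normal(size=40)
        ranking = rank_svm_rfe(x, y, svr_spec())
        assert sorted(ranking.order) == list(range(23))

    def test_deterministic(self, rng):
        x = rng.normal(size=(50, 15))
        y = x[:, 0] + rng.normal(size=50)
        a = rank_svm_rfe(x, y, svr_spec())
        b = rank_svm_rfe(x, y, svr_spec())
        np.testing.assert_array_equal(a.order, b.order)

    def test_one_at_a_time_mode(self, rng):
        x = rng.normal(size=(60, 8))
        y = x[:, 2] + 0.1 * rng.normal(size=60)
        ranking = rank_svm_rfe(x, y, svr_spec(rfe_step_fraction=0.0))
        assert ranking.order[0] == 2


class TestRandomForest:
    def test_oob_fraction_near_one_over_e(self):
        value = expected_oob_fraction(5000, n_draws=50, seed=1)
        assert abs(value - (1 - 1 / 5000) ** 5000) < 0.005

    def test_pure_noise_oob_matches_target_variance(self, rng):
        x = rng.normal(size=(500, 10))
        y = rng.normal(size=500)
        _, oob = fit_random_forest(x, y, RegressorSpec(
            family="random_forest", ntree=200, seed=2))
        assert abs(oob - y.var()) / y.var() < 0.15

    def test_step_function_oob_far_below_variance(self, rng):
        x = rng.normal(size=(500, 10))
        y = (x[:, 0] > 0) * 5.0
        _, oob = fit_random_forest(x, y, RegressorSpec(
            family="random_forest", ntree=200, seed=3))
        assert oob < 0.2 * y.var()

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_random_forest(rng.normal(size=(4, 3)), np.arange(4.0),
                              RegressorSpec(family="random_forest", ntree=10))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(300, 8))
    y = 2 * x[:, 4] + 0.3 * rng.normal(size=300)
    model, _ = fit_random_forest(x, y, RegressorSpec(
        family="random_forest", ntree=150, seed=5))
    return model


class TestPermutationImportance:
    def test_informative_feature_ranked_first(self, fitted):
        ranking = rf_permutation_importance(fitted, seed=0)
        assert ranking.order[0] == 4

    def test_identity_permutation_gives_exact_zero(self, fitted):
        ranking = rf_permutation_importance(
            fitted, seed=0, permutation_fn=lambda r, n: np.arange(n))
        assert np.all(ranking.scores == 0.0)

    def test_irrelevant_importance_centred_on_zero(self):
        # sign test over independent refits: noise features should be
        # positive or negative with roughly equal probability
        signs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(150, 5))
            y = 2 * x[:, 0] + 0.5 * rng.normal(size=150)
            model, _ = fit_random_forest(x, y, RegressorSpec(
                family="random_forest", ntree=60, seed=seed))
            imp = rf_permutation_importance(model, seed=seed)
            noise_scores = imp.scores[np.isin(imp.order, [1, 2, 3, 4])]
            signs.extend(np.sign(noise_scores))
        mean_noise = np.mean(signs)
        assert abs(mean_noise) < 0.6


class TestLassoInnerCV:
    def test_huge_penalty_empties_support(self, rng):
        x = rng.normal(size=(60, 10))
        y = rng.normal(size=60)
        _, support, _ = fit_lasso_inner_cv(x, y, lasso_spec([1e6]))
        assert not support.any()

    def test_zero_penalty_matches_ols(self, rng):
        x = rng.normal(size=(50, 4))
        y = x @ np.array([1.0, -0.5, 2.0, 0.0]) + 0.1 * rng.normal(size=50)
        fit, _, _ = fit_lasso_inner_cv(x, y, lasso_spec([0.0]))
        xs = (x - x.mean(0)) / x.std(0)
        design = np.hstack([np.ones((50, 1)), xs])
        ols = np.linalg.lstsq(design, y, rcond=None)[0][1:]
        np.testing.assert_allclose(fit.coef_std, ols, atol=1e-6)

    def test_orthonormal_design_soft_threshold(self, rng):
        n, p = 64, 8
        q, _ = np.linalg.qr(np.hstack([np.ones((n, 1)),
                                       rng.normal(size=(n, p))]))
        x = q[:, 1:] * np.sqrt(n)  # centred, unit variance, X'X = nI
        beta = np.array([2.0, -1.5, 1.0, 0, 0, 0.5, 0, 0])
        y = x @ beta + 0.1 * rng.normal(size=n)
        alpha = 0.3
        fit, _, _ = fit_lasso_inner_cv(x, y, lasso_spec([alpha]))
        b_ols = x.T @ (y - y.mean()) / n
        soft = np.sign(b_ols) * np.maximum(np.abs(b_ols) - alpha, 0)
        np.testing.assert_allclose(fit.coef_std, soft, atol=1e-10)

    def test_inner_cv_picks_sensible_penalty(self, rng):
        x = rng.normal(size=(120, 30))
        y = x[:, 0] * 2 + 0.5 * rng.normal(size=120)
        fit, support, ranking = fit_lasso_inner_cv(
            x, y, lasso_spec(np.logspace(-3, 2, 8), seed=1))
        assert support[0]
        assert ranking.order[0] == 0

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            lasso_spec([])


def test_all_rankers_find_planted_feature():
    """Power check: every ranker puts a strong planted linear feature in
    the top 5% at n=300, P=100."""
    for seed in range(3):
        rng = np.random.default_rng(200 + seed)
        x = rng.normal(size=(300, 100))
        y = 5 * x[:, 42] + rng.normal(size=300)
        r_svm = rank_svm_rfe(x, y, svr_spec(seed=seed))
        model, _ = fit_random_forest(x, y, RegressorSpec(
            family="random_forest", ntree=100, seed=seed))
        r_rf = rf_permutation_importance(model, seed=seed)
        _, _, r_lasso = fit_lasso_inner_cv(
            x, y, lasso_spec(np.logspace(-3, 1, 6), seed=seed))
        for ranking in (r_svm, r_rf, r_lasso):
            assert list(ranking.order).index(42) < 5
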