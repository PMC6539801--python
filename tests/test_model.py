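import numpy as np
import pytest

from sirmsmix.model import (
    GAConfig,
    QsprModel,
    SingularDesignError,
    fit_mlr,
    ga_select,
    incremental_subset_search,
    loo_residuals,
    mean_effects,
    predict,
    q2_loo,
    rmsecv_loo,
)


def normal_equations(X, y):
    """Brute-force oracle: beta = (A'A)^-1 A'y with intercept column."""
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.inv(A.T @ A) @ A.T @ y


def loo_refit_loop(X, y):
    """Brute-force oracle: literally refit n times leaving one sample out."""
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta = normal_equations(X[mask], y[mask])
        out[i] = y[i] - (beta[0] + X[i] @ beta[1:])
    return out


class TestFitMlr:
    def test_exact_linear_data_gives_perfect_fit(self):
        X = np.arange(5.0).reshape(-1, 1)
        y = 2.0 + 3.0 * X[:, 0]
        model = fit_mlr(X, y)
        assert model.stats["r2"] == pytest.approx(1.0)
        assert model.stats["s"] == pytest.approx(0.0, abs=1e-10)
        assert model.intercept == pytest.approx(2.0)

    def test_no_residual_degrees_of_freedom_rejected(self):
        X = np.random.default_rng(0).normal(size=(3, 2))
        with pytest.raises(ValueError):
            fit_mlr(X, np.array([1.0, 2.0, 3.0]))

    def test_coefficients_match_normal_equations_oracle(self, small_regression):
        X, y = small_regression
        model = fit_mlr(X, y)
        beta = normal_equations(X, y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        fitted = [model.coefficients[nm] for nm in model.names]
        assert np.allclose(fitted, beta[1:], atol=1e-10)

    def test_collinear_columns_named_in_error(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularDesignError):
            fit_mlr(X, rng.normal(size=10))

    def test_statistics_definitions(self, small_regression):
        X, y = small_regression
        model = fit_mlr(X, y)
        A = np.column_stack([np.ones(len(X)), X])
        resid = y - A @ normal_equations(X, y)
        rss, tss = resid @ resid, ((y - y.mean()) ** 2).sum()
        n, p = X.shape
        assert model.stats["r2"] == pytest.approx(1 - rss / tss)
        assert model.stats["s"] == pytest.approx(np.sqrt(rss / (n - p - 1)))
        r2 = model.stats["r2"]
        assert model.stats["f"] == pytest.approx((r2 / p) / ((1 - r2) / (n - p - 1)))


class TestLeaveOneOut:
    def test_noiseless_linear_data_has_zero_rmsecv(self):
        X = np.arange(8.0).reshape(-1, 1)
        y = 1.0 + 0.5 * X[:, 0]
        assert rmsecv_loo(X, y) == pytest.approx(0.0, abs=1e-9)

    def test_hat_trick_equals_explicit_refit_loop(self, small_regression):
        X, y = small_regression
        assert np.allclose(loo_residuals(X, y), loo_refit_loop(X, y), atol=1e-10)

    def test_rmsecv_nonnegative_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X = rng.normal(size=(9, 2))
            y = rng.normal(size=9)
            assert rmsecv_loo(X, y) >= 0.0

    def test_q2_loo_equals_refit_loop_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 1))
        y = 4.0 + X[:, 0] + rng.normal(scale=0.5, size=6)
        press = (loo_refit_loop(X, y) ** 2).sum()
        expected = 1 - press / ((y - y.mean()) ** 2).sum()
        assert q2_loo(X, y) == pytest.approx(expected, abs=1e-12)

    def test_q2_loo_perfect_for_noiseless_data(self):
        X = np.arange(7.0).reshape(-1, 1)
        assert q2_loo(X, 3 * X[:, 0] + 1) == pytest.approx(1.0)

    def test_r2_dominates_q2_loo(self, tiny_dataset):
        active = tiny_dataset.truth.active_names
        model = fit_mlr(tiny_dataset.matrix.frame[active], tiny_dataset.y)
        assert model.stats["r2"] >= model.stats["q2_loo"]


def _planted(n=60, p=40, k=3, noise=0.0, seed=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    active = sorted(rng.choice(p, size=k, replace=False).tolist())
    beta = rng.uniform(2.0, 4.0, size=k) * rng.choice([-1, 1], size=k)
    y = 10.0 + X[:, active] @ beta + rng.normal(scale=noise, size=n)
    return X, y, active


class TestGaSelect:
    def test_recovers_noiseless_planted_subset(self):
        X, y, active = _planted()
        res = ga_select(X, y, 3, GAConfig(seed=1))
        assert sorted(res.indices) == active
        assert res.rmsecv == pytest.approx(0.0, abs=1e-8)

    def test_single_column_matches_exhaustive_search(self):
        X, y, _ = _planted(n=30, p=12, k=1, noise=0.5, seed=9)
        res = ga_select(X, y, 1, GAConfig(seed=2))
        best = min(range(12), key=lambda j: rmsecv_loo(X[:, [j]], y))
        assert res.indices == (best,)

    def test_seed_reproducibility(self):
        X, y, _ = _planted(noise=1.0)
        r1 = ga_select(X, y, 3, GAConfig(seed=11))
        r2 = ga_select(X, y, 3, GAConfig(seed=11))
        assert r1.indices == r2.indices and r1.rmsecv == r2.rmsecv

    def test_dominates_random_subsets(self):
        X, y, _ = _planted(noise=2.0, seed=13)
        res = ga_select(X, y, 3, GAConfig(seed=3))
        rng = np.random.default_rng(99)
        for _ in range(50):
            cols = rng.choice(X.shape[1], size=3, replace=False)
            assert res.rmsecv <= rmsecv_loo(X[:, cols], y) + 1e-12

    def test_infeasible_size_rejected(self):
        X, y, _ = _planted()
        with pytest.raises(ValueError):
            ga_select(X, y, 40, GAConfig(seed=0))


class TestIncrementalSearch:
    def test_stops_at_planted_size_two(self):
        # n large enough that chance LOO gains from a spurious third
        # column stay below the 2% stopping tolerance
        rng = np.random.default_rng(21)
        X = rng.normal(size=(150, 30))
        y = 5.0 + 3.0 * X[:, 4] - 2.0 * X[:, 17] + rng.normal(scale=1.0, size=150)
        model = incremental_subset_search(X, y, GAConfig(seed=4), k_max=5)
        assert model.p == 2
        assert set(model.names) == {"x4", "x17"}

    def test_pure_noise_stops_at_one(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(60, 20))
        y = rng.normal(size=60)
        model = incremental_subset_search(X, y, GAConfig(seed=5), k_max=5)
        assert model.p == 1

    def test_zero_tolerance_runs_to_k_max(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(60, 15))
        y = X[:, 0] + rng.normal(size=60)
        model = incremental_subset_search(X, y, GAConfig(seed=6), k_max=4, tol=0.0)
        assert model.p == 4


class TestMeanEffects:
    def test_single_descriptor_model_has_full_effect(self):
        X = np.abs(np.random.default_rng(2).normal(size=(10, 1))) + 1
        model = fit_mlr(X, 2 + 3 * X[:, 0])
        report = mean_effects(model, X)
        assert report.effects[model.names[0]] == pytest.approx(100.0)

    def test_effects_sum_to_hundred(self, tiny_dataset):
        active = tiny_dataset.truth.active_names
        model = fit_mlr(tiny_dataset.matrix.frame[active], tiny_dataset.y)
        report = mean_effects(model, tiny_dataset.matrix.frame)
        assert sum(report.effects.values()) == pytest.approx(100.0, abs=1e-9)

    def test_centered_variant_differs_from_raw(self, tiny_dataset):
        active = tiny_dataset.truth.active_names
        model = fit_mlr(tiny_dataset.matrix.frame[active], tiny_dataset.y)
        raw = mean_effects(model, tiny_dataset.matrix.frame)
        centred = mean_effects(model, tiny_dataset.matrix.frame, centered=True)
        assert sum(centred.effects.values()) == pytest.approx(100.0, abs=1e-9)
        assert raw.effects != centred.effects


class TestPredict:
    def test_zero_descriptors_return_intercept(self):
        model = QsprModel(
            intercept=700.630,
            coefficients={"X1": 36.735},
            names=["X1"],
            stats={},
        )
        assert predict(model, np.zeros((1, 1)))[0] == pytest.approx(700.630)

    def test_unit_vector_adds_one_coefficient(self):
        model = QsprModel(
            intercept=700.630,
            coefficients={"X1": 36.735, "X2": -56.130},
            names=["X1", "X2"],
            stats={},
        )
        yhat = predict(model, np.array([[1.0, 0.0]]))
        assert yhat[0] == pytest.approx(737.365)

    def test_training_rows_of_noiseless_model_reproduced_exactly(self):
        X, y, active = _planted(noise=0.0)
        model = fit_mlr(X[:, active], y)
        assert np.allclose(predict(model, X[:, active]), y, atol=1e-8)

    def test_missing_column_named_in_error(self, tiny_dataset):
        active = tiny_dataset.truth.active_names
        model = fit_mlr(tiny_dataset.matrix.frame[active], tiny_dataset.y)
        with pytest.raises(KeyError, match=active[0][:8].replace("|", "\\|")):
            predict(model, tiny_dataset.matrix.frame.drop(columns=[active[0]]))
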