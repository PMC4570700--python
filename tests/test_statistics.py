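import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LinearRegression

from autoqsar import (
    CVScheme,
    CVMetrics,
    adjusted_r_squared,
    cv_statistics,
    evaluate_split,
    hat_values,
    make_cv_folds,
    r_squared,
    rmse,
    standardized_rmse,
    tune_and_fit,
    method_spec,
)
from autoqsar.dataset import Dataset
from autoqsar.resampling import iter_resamples
from autoqsar.stats import STAT_COLUMNS, r_squared_fit


def brute_rmse(obs, pred):
    return math.sqrt(sum((o - p) ** 2 for o, p in zip(obs, pred)) / len(obs))


def brute_pearson(obs, pred):
    n = len(obs)
    mo = sum(obs) / n
    mp = sum(pred) / n
    num = sum((o - mo) * (p - mp) for o, p in zip(obs, pred))
    den = math.sqrt(sum((o - mo) ** 2 for o in obs) * sum((p - mp) ** 2 for p in pred))
    return num / den


class TestRmse:
    def test_perfect(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_offset_pairs(self):
        assert rmse([0.0, 0.0], [1.0, 1.0]) == pytest.approx(1.0)
        assert rmse([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(Exception):
            rmse([1.0], [1.0, 2.0])


class TestRSquared:
    def test_affine_invariance(self):
        obs = np.arange(10.0)
        assert r_squared(obs, 2 * obs + 5) == pytest.approx(1.0)

    def test_orthogonalized_prediction_near_zero(self):
        rng = np.random.default_rng(8)
        obs = rng.standard_normal(100)
        raw = rng.standard_normal(100)
        oc = obs - obs.mean()
        pred = raw - (raw - raw.mean()) @ oc / (oc @ oc) * oc  # residualized vs obs
        assert abs(r_squared(obs, pred)) < 0.02

    def test_hand_computation(self):
        obs, pred = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]
        assert r_squared(obs, pred) == pytest.approx(brute_pearson(obs, pred) ** 2)

    def test_zero_variance_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(r_squared([1.0, 1.0], [1.0, 2.0]))


class TestAdjustedRSquared:
    def test_perfect_fit_fixed_point(self):
        assert adjusted_r_squared(1.0, 30, 5) == pytest.approx(1.0)

    def test_hand_value(self):
        assert adjusted_r_squared(0.5, 12, 1) == pytest.approx(0.45, abs=1e-12)

    def test_can_be_negative(self):
        assert adjusted_r_squared(0.0, 11, 1) == pytest.approx(-1.0 / 9.0)

    def test_undefined_when_n_small(self):
        with pytest.warns(UserWarning):
            assert math.isnan(adjusted_r_squared(0.9, 3, 2))

    def test_monotone_decreasing_in_p(self):
        vals = [adjusted_r_squared(0.7, 50, p) for p in range(1, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestStandardizedRmse:
    def test_perfect(self):
        assert standardized_rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_mean_prediction_identity(self):
        # RMSE of the mean predictor is the population sd, so the ratio is
        # sqrt((n-1)/n); at n=10 that is ~0.9487
        rng = np.random.default_rng(1)
        obs = rng.standard_normal(10)
        pred = np.full(10, obs.mean())
        expected = math.sqrt(9 / 10)
        assert standardized_rmse(obs, pred) == pytest.approx(expected)
        assert expected == pytest.approx(0.9487, abs=5e-5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        obs = rng.standard_normal(20)
        pred = obs + rng.standard_normal(20)
        assert standardized_rmse(2 * obs, 2 * pred) == pytest.approx(
            standardized_rmse(obs, pred)
        )


class TestCvStatistics:
    def test_mean_of_two(self):
        m = CVMetrics("repeated_kfold", [0.4, 0.6], [0.8, 0.9])
        rmse_cv, r2_cv = cv_statistics(m)
        assert rmse_cv == pytest.approx(0.5)
        assert r2_cv == pytest.approx(0.85)

    def test_loo_pooled_residuals(self):
        obs = np.array([1.0, -1.0, 1.0, -1.0])
        m = CVMetrics("loo", [], [], pooled_obs=obs, pooled_pred=np.zeros(4))
        rmse_cv, _ = cv_statistics(m)
        assert rmse_cv == pytest.approx(1.0)

    def test_singleton(self):
        m = CVMetrics("repeated_kfold", [0.3], [0.7])
        assert cv_statistics(m) == (pytest.approx(0.3), pytest.approx(0.7))


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(min_value=0, max_value=10**6))
def test_metrics_agree_with_brute_force(seed):
    """rmse and r_squared match explicit-loop recomputation on random vectors."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    obs = rng.standard_normal(n)
    pred = obs + rng.standard_normal(n) * rng.uniform(0.1, 2)
    assert rmse(obs, pred) == pytest.approx(brute_rmse(obs, pred), rel=1e-12)
    assert r_squared(obs, pred) == pytest.approx(brute_pearson(obs, pred) ** 2, rel=1e-12)
    sd = np.std(obs, ddof=1)
    assert standardized_rmse(obs, pred) == pytest.approx(brute_rmse(obs, pred) / sd, rel=1e-12)


def test_loo_matches_hat_matrix_closed_form():
    """Loop-computed LOO predictions for OLS equal obs − e/(1−h) from one fit.

    The hat-matrix identity is the module's primary oracle: it validates the
    whole generic CV loop against linear-model theory.
    """
    rng = np.random.default_rng(60)
    n, p = 60, 5
    X = rng.standard_normal((n, p))
    y = X @ rng.uniform(0.5, 2.0, p) + 0.3 * rng.standard_normal(n)

    ids = np.arange(n)
    folds = make_cv_folds(ids, CVScheme("loo"), seed=0)
    loo_pred = np.empty(n)
    for hold, keep in iter_resamples(ids, folds):
        est = LinearRegression().fit(X[keep], y[keep])
        loo_pred[hold[0]] = est.predict(X[hold])[0]

    est = LinearRegression().fit(X, y)
    e = y - est.predict(X)
    h = hat_values(X, add_intercept=True)
    closed = y - e / (1 - h)
    np.testing.assert_allclose(loo_pred, closed, atol=1e-8)


class TestEvaluateSplit:
    def fit_lm(self, ds_train):
        spec = method_spec("LM")
        scheme = CVScheme("repeated_kfold", folds=5, repeats=1)
        return tune_and_fit(spec, ds_train.X, ds_train.y, scheme, seed=0,
                            feature_names=ds_train.feature_names)

    def test_noiseless_linear_is_exact(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 1.0
        ds = Dataset("y", y, ["a", "b", "c"], X)
        train, test = ds.subset_rows(np.arange(30)), ds.subset_rows(np.arange(30, 40))
        model, cvm = self.fit_lm(train)
        rec = evaluate_split(model, train, test, cvm, 1, "repeated_kfold")
        assert rec.r2_test == pytest.approx(1.0)
        assert rec.rmse_test == pytest.approx(0.0, abs=1e-10)
        assert rec.n_features == 3

    def test_permuted_response_destroys_association(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 4))
            y = rng.permutation(X @ np.ones(4) + 0.1 * rng.standard_normal(200))
            ds = Dataset("y", y, [f"f{i}" for i in range(4)], X)
            train = ds.subset_rows(np.arange(150))
            test = ds.subset_rows(np.arange(150, 200))
            model, cvm = self.fit_lm(train)
            rec = evaluate_split(model, train, test, cvm, 1, "repeated_kfold")
            assert rec.r2_test < 0.1

    def test_record_has_all_17_fields(self, tiny_exact_ds):
        ds = tiny_exact_ds
        train, test = ds.subset_rows(np.arange(15)), ds.subset_rows(np.arange(15, 20))
        model, cvm = self.fit_lm(train)
        rec = evaluate_split(model, train, test, cvm, 1, "repeated_kfold")
        row = rec.as_row()
        assert tuple(row) == STAT_COLUMNS
        assert len(row) == 17

    def test_fit_r2_uses_coefficient_of_determination(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        tss = np.sum((obs - obs.mean()) ** 2)
        rss = np.sum((obs - pred) ** 2)
        assert r_squared_fit(obs, pred) == pytest.approx(1 - rss / tss)
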