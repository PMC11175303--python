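"""PLS1, cross-validation, variable selection and metrics, with independent oracles."""

import numpy as np
import pandas as pd
import pytest

from piezonose.preprocessing import BLOCK_PARAM
from piezonose.regression import (
    cross_validate,
    delta_percent,
    fit_pls,
    predict,
    report_metrics,
    select_variables,
    train_indicator,
)
from piezonose.signal_io import RunConfig
from piezonose.types import lg


def param_frame(X):
    """Wrap an array as center-only (parameter-block) features p01_, p02_, ..."""
    return pd.DataFrame(X, columns=[f"p{j:02d}_x" for j in range(X.shape[1])])


@pytest.fixture()
def random_data():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(15, 6))
    b_true = np.array([1.5, -2.0, 0.0, 0.5, 0.0, 1.0])
    y = X @ b_true + 0.1 * rng.normal(size=15)
    return param_frame(X), y


class TestFitPLS:
    def test_single_informative_column_one_factor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = param_frame(np.column_stack([x, np.full(30, 2.0), np.full(30, -1.0)]))
        y = 3.0 * x + 1.0
        model = fit_pls(X, y, 1)
        yhat, _ = predict(model, X)
        assert np.max(np.abs(yhat - y)) < 1e-9

    def test_full_rank_equals_pseudo_inverse_least_squares(self, random_data):
        X, y = random_data
        model = fit_pls(X, y, n_factors=6)
        yhat, _ = predict(model, X)
        # independent oracle: centered least squares via pseudo-inverse
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        yc = y - y.mean()
        oracle = y.mean() + Xc @ np.linalg.pinv(Xc) @ yc
        assert np.allclose(yhat, oracle, atol=1e-8)

    def test_agrees_with_sklearn_nipals(self, random_data):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_data
        model = fit_pls(X, y, n_factors=3)
        ref = sklearn.PLSRegression(n_components=3, scale=False)
        ref.fit(X.to_numpy(), y)
        yhat, _ = predict(model, X)
        assert np.allclose(yhat, ref.predict(X.to_numpy()).ravel(), atol=1e-8)

    def test_row_permutation_leaves_coefficients(self, random_data):
        X, y = random_data
        perm = np.random.default_rng(1).permutation(len(y))
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(X.iloc[perm].reset_index(drop=True), y[perm], 3)
        assert np.allclose(m1.coef, m2.coef, atol=1e-10)

    def test_constant_response_rejected(self, random_data):
        X, _ = random_data
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, np.ones(len(X)), 2)

    def test_too_many_factors_rejected(self, random_data):
        X, y = random_data
        with pytest.raises(ValueError, match="n_factors"):
            fit_pls(X, y, 20)


class TestCrossValidation:
    def test_matches_naive_refit_loop(self, random_data):
        X, y = random_data
        max_f = 4
        cv = cross_validate(X, y, max_f)
        # brute-force oracle: refit a fresh model (scaling included) per row
        naive = np.zeros((len(y), max_f))
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            for f in range(1, max_f + 1):
                m = fit_pls(X.iloc[keep], y[keep], f)
                naive[i, f - 1] = predict(m, X.iloc[[i]])[0][0]
        rmsep_naive = np.sqrt(np.mean((naive - y[:, None]) ** 2, axis=0))
        assert np.allclose(cv.rmsep_by_factor.to_numpy(), rmsep_naive, atol=1e-10)

    def test_noiseless_one_factor_data_selects_one_factor(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=20)
        load = np.array([1.0, -0.5, 2.0, 0.3])
        X = param_frame(np.outer(t, load))
        y = 2.0 * t + 5.0
        cv = cross_validate(X, y, 4)
        assert cv.n_factors == 1
        assert cv.rmsep_by_factor[1] < 1e-8

    def test_deterministic(self, random_data):
        X, y = random_data
        a = cross_validate(X, y, 4)
        b = cross_validate(X, y, 4)
        assert a.n_factors == b.n_factors
        assert np.array_equal(a.predictions, b.predictions)

    def test_too_many_factors_rejected(self, random_data):
        X, y = random_data
        with pytest.raises(ValueError):
            cross_validate(X, y, len(y))


class TestVariableSelection:
    def test_keep_all_configuration(self, random_data):
        X, y = random_data
        cfg = RunConfig(vs_coef_quantile=0.0, vs_leverage_multiplier=float("inf"))
        mask, _ = select_variables(X, y, cfg)
        assert mask.all()

    def test_noise_columns_removed_with_high_probability(self):
        """Across seeded replicates, appended pure-noise columns are dropped
        with probability >= 0.9 while informative columns survive."""
        removed = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            signal = rng.normal(size=(n, 5))
            noise = rng.normal(size=(n, 20))
            X = param_frame(np.hstack([signal, noise]))
            y = signal @ np.array([2.0, -1.5, 1.0, 0.8, -1.2]) + 0.2 * rng.normal(size=n)
            mask, _ = select_variables(X, y, RunConfig())
            removed.append((~mask[X.columns[5:]]).mean())
            assert mask[X.columns[:5]].all()
        assert np.mean(removed) >= 0.9

    def test_deterministic(self, random_data):
        X, y = random_data
        m1, l1 = select_variables(X, y, RunConfig())
        m2, l2 = select_variables(X, y, RunConfig())
        assert m1.equals(m2)
        assert l1 == l2


class TestPredict:
    def test_saturated_model_reproduces_noiseless_training(self):
        rng = np.random.default_rng(21)
        X = param_frame(rng.normal(size=(15, 6)))
        y = X.to_numpy() @ np.array([1.5, -2.0, 0.0, 0.5, 0.3, 1.0])
        model = fit_pls(X, y, 6)
        model.rmsep = 0.1
        yhat, dev = predict(model, X)
        assert np.max(np.abs(y - yhat)) < 1e-9
        assert np.all(dev >= model.rmsep)

    def test_deviation_never_below_rmsep(self, random_data):
        X, y = random_data
        model = fit_pls(X, y, 2)
        model.rmsep = 0.5
        X_far = X + 10.0
        _, dev = predict(model, X_far)
        assert np.all(dev >= 0.5)
        # far samples have higher leverage, hence wider deviations
        _, dev_near = predict(model, X)
        assert dev.mean() > dev_near.mean()

    def test_missing_columns_rejected(self, random_data):
        X, y = random_data
        model = fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="missing"):
            predict(model, X.iloc[:, :3])

    def test_heldout_coverage_at_least_two_thirds(self):
        """RMSEP-scaled deviations cover >= 2/3 of independent held-out samples."""
        rng = np.random.default_rng(11)
        n_train, n_test, p = 30, 12, 8
        coefs = np.array([2.0, -1.0, 1.5, 0.0, 0.5, 0.0, -0.8, 0.3])
        X = param_frame(rng.normal(size=(n_train + n_test, p)))
        y = X.to_numpy() @ coefs + 0.3 * rng.normal(size=n_train + n_test)
        Xtr, ytr = X.iloc[:n_train], y[:n_train]
        cv = cross_validate(Xtr, ytr, 6)
        model = fit_pls(Xtr, ytr, cv.n_factors)
        model.rmsep = float(cv.rmsep_by_factor[cv.n_factors])
        yhat, dev = predict(model, X.iloc[n_train:])
        covered = np.abs(yhat - y[n_train:]) <= dev
        assert covered.mean() >= 2 / 3


class TestMetrics:
    def test_relative_error_reconstruction_total_count(self):
        # printed model error 0.390 against the largest training lg count 7.99
        assert round(delta_percent(0.390, lg(9.8e7)), 1) == 4.9

    def test_relative_error_reconstruction_yeast(self):
        assert round(delta_percent(0.535, lg(3.4e4))) == 12

    def test_perfect_predictions(self, random_data):
        X, y = random_data
        cv = cross_validate(X, y, 6)
        cv.predictions = y.copy()
        model = fit_pls(X, y, 6)
        report = report_metrics(cv, y, model)
        assert report.rmsep == 0.0
        assert report.r_squared == pytest.approx(1.0)
        assert report.delta_pct == 0.0

    def test_train_indicator_end_to_end(self, random_data):
        X, y = random_data
        im = train_indicator(X, y + 10.0, "demo", RunConfig(vs_max_iter=3))
        assert im.report.rmsep > 0
        assert im.report.r_squared <= 1.0
        assert im.model.rmsep == pytest.approx(
            im.report.rmsep_by_factor[im.report.n_factors]
        )
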