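"""PLS1 engine: oracle equivalences, CV plans, latent-variable selection,
and the standardized prediction metrics."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from granupls.evaluate import ReferenceStats
from granupls.pls import (
    block_plan,
    cross_validate,
    fit_pls,
    loo_plan,
    metrics,
    predict,
    select_n_lv,
    sequential_plan,
)


def _problem(seed, n=20, p=10, noise=0.01):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_exact_linear_single_column(self):
        rng = np.random.default_rng(3)
        # centered orthogonal columns: the first weight vector then points
        # exactly along the informative column (autoscaling keeps columns
        # orthogonal only when they are already centered)
        G = rng.normal(size=(30, 6))
        X, _ = np.linalg.qr(G - G.mean(axis=0))
        y = 2.5 * X[:, 3] + 1.0
        m = fit_pls(X, y, 1)
        # one latent variable suffices when y is exactly linear in one column
        assert np.sqrt(np.mean((predict(m, X) - y) ** 2)) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_least_squares(self, seed):
        X, y = _problem(seed)
        m = fit_pls(X, y, 10)
        A = np.column_stack([np.ones(len(y)), X])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(predict(m, X), A @ coef, atol=1e-8)

    @pytest.mark.parametrize("n_lv", [1, 2, 3, 5])
    def test_matches_reference_implementation(self, n_lv):
        X, y = _problem(42)
        m = fit_pls(X, y, n_lv)
        sk = PLSRegression(n_components=n_lv, scale=True).fit(X, y)
        np.testing.assert_allclose(predict(m, X), sk.predict(X).ravel(), atol=1e-8)

    def test_row_permutation_invariance(self, rng):
        X, y = _problem(11)
        perm = rng.permutation(len(y))
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(X[perm], y[perm], 3)
        np.testing.assert_allclose(m1.B, m2.B, atol=1e-10)

    def test_n_lv_bounds_enforced(self):
        X, y = _problem(0)
        with pytest.raises(ValueError):
            fit_pls(X, y, 11)
        with pytest.raises(ValueError):
            fit_pls(X, y, 0)

    def test_predict_checks_columns_and_handles_single_row(self):
        X, y = _problem(1)
        m = fit_pls(X, y, 2)
        single = predict(m, X[0])
        assert single.shape == (1,)
        np.testing.assert_allclose(single[0], X[0] @ m.B + m.intercept)
        with pytest.raises(ValueError):
            predict(m, X[:, :5])


class TestCrossValidation:
    def test_loo_matches_explicit_loop(self):
        X, y = _problem(5, n=15, p=4)
        plan = loo_plan(15)
        rmsecv, resid = cross_validate(X, y, plan, 2)
        errs = np.empty(15)
        for i in range(15):
            tr = np.arange(15) != i
            m = fit_pls(X[tr], y[tr], 2)
            errs[i] = y[i] - predict(m, X[i : i + 1])[0]
        np.testing.assert_allclose(resid, errs, atol=1e-10)
        assert rmsecv == pytest.approx(np.sqrt(np.mean(errs**2)), abs=1e-10)

    def test_sequential_plan_is_index_arithmetic(self):
        plan = sequential_plan(10, 3)
        np.testing.assert_array_equal(plan.folds, np.arange(10) % 3)

    def test_block_plan_partitions_with_remainder_leading(self):
        plan = block_plan(101, 10)
        sizes = np.bincount(plan.folds)
        assert sizes[0] == 11 and np.all(sizes[1:] == 10)
        plan = block_plan(100, 10)
        assert np.all(np.bincount(plan.folds) == 10)

    def test_fold_too_small_for_components_raises(self):
        X, y = _problem(2, n=8, p=6)
        with pytest.raises(ValueError, match="training rows"):
            cross_validate(X, y, block_plan(8, 2), 5)

    def test_low_noise_rmsecv_close_to_rmsec(self):
        # plenty of rows, little noise: CV error matches calibration error
        X, y = _problem(9, n=400, p=8, noise=0.05)
        m = fit_pls(X, y, 8)
        rmsec = np.sqrt(np.mean((y - predict(m, X)) ** 2))
        rmsecv, _ = cross_validate(X, y, sequential_plan(400, 10), 8)
        assert rmsecv / rmsec == pytest.approx(1.0, abs=0.05)


class TestSelectNLV:
    def test_matches_exhaustive_scan(self):
        X, y = _problem(7, n=40, p=6, noise=0.5)
        plan = sequential_plan(40, 5)
        best = select_n_lv(X, y, plan, 6)
        scan = [cross_validate(X, y, plan, k)[0] for k in range(1, 7)]
        assert best == int(np.argmin(scan)) + 1

    def test_parsimony_on_flat_curve(self):
        # y independent of X: every component count is equally (un)helpful,
        # so the smallest model is returned
        rng = np.random.default_rng(0)
        X = np.repeat(rng.normal(size=(20, 1)), 4, axis=1)
        X = X + 1e-12 * rng.normal(size=X.shape)
        y = rng.normal(size=20)
        assert select_n_lv(X, y, loo_plan(20), 4) == 1


class TestMetrics:
    REF = ReferenceStats(sd=138.6, min=52.4, max=824.7, iqr=192.2, lab_error=70.3)

    def test_ratio_formulas_against_reference_population(self):
        # choose predictions with an exact RMSEP of 68.3
        obs = np.zeros(4)
        pred = np.full(4, 68.3)
        m = metrics(obs, pred, self.REF)
        assert m.rmsep == pytest.approx(68.3)
        assert m.rpd == pytest.approx(138.6 / 68.3)
        assert round(m.rpd, 2) == 2.03
        assert m.rer == pytest.approx(772.3 / 68.3)
        assert m.prl == pytest.approx(68.3 / 70.3)
        assert m.rpiq == pytest.approx(192.2 / 68.3)

    def test_rpd_identity_exact(self, rng):
        obs = rng.normal(size=50)
        pred = obs + rng.normal(size=50)
        m = metrics(obs, pred, self.REF)
        assert m.rpd * m.rmsep == pytest.approx(self.REF.sd, abs=1e-12)

    def test_perfect_prediction(self):
        obs = np.arange(5.0)
        m = metrics(obs, obs)
        assert m.rmsep == 0.0 and m.r2_test == 1.0

    def test_zero_rmsep_with_ratios_guarded(self):
        obs = np.arange(5.0)
        with pytest.raises(ZeroDivisionError):
            metrics(obs, obs, self.REF)
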