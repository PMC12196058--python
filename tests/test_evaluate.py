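"""Split plans, batch folds, model comparison plumbing and importance tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granupls.data import PARAMETER_NAMES, SIZE_NAMES
from granupls.evaluate import (
    ReferenceStats,
    block_cv_plan,
    coefficient_importance,
    lod_holdout,
    ma1_split,
    ma1add_split,
    ma2_folds,
    paired_test,
    predictor_matrix,
    run_comparison,
)
from granupls.pls import fit_pls
from granupls.simulate import SimConfig, simulate_batch, simulate_campaign


def _batch(n=100, seed=0, spray_fraction=0.7):
    cfg = SimConfig(n_batches=1, rows_per_batch=(n, n), seed=seed,
                    spray_fraction=spray_fraction)
    b, _ = simulate_batch(cfg, "t", seed)
    return b


class TestMA1Split:
    def test_fig2_sizes(self):
        b = _batch(2644)
        plan = ma1_split(b)
        assert plan.external_test.size == 264
        assert plan.external_test[0] == 2644 - 264

    def test_hundred_row_arithmetic(self):
        plan = ma1_split(_batch(100))
        assert plan.external_test.size == 10
        assert plan.internal_test.size == 9
        assert plan.train.size == 81

    @given(n=st.integers(20, 3000))
    @settings(max_examples=40, deadline=None)
    def test_partition_property(self, n):
        # the split is pure index arithmetic on the row count
        class Fake:
            batch_id = "f"
            n_rows = n
        p = ma1_split(Fake())
        allidx = np.sort(np.concatenate([p.train, p.internal_test, p.external_test]))
        np.testing.assert_array_equal(allidx, np.arange(n))
        assert p.external_test.size == n // 10
        # external set is a time-order suffix
        assert p.external_test[0] == n - n // 10

    def test_too_short_batch_rejected(self):
        class Fake:
            batch_id = "f"
            n_rows = 12
        with pytest.raises(ValueError):
            ma1_split(Fake())


class TestMA1AddSplit:
    def test_external_is_half_the_terminal_drying_run(self):
        b = _batch(200, spray_fraction=0.5)  # 100 drying rows
        plan = ma1add_split(b)
        assert plan.external_test.size == 50
        assert plan.external_test[0] == 150
        allidx = np.sort(np.concatenate([plan.train, plan.internal_test,
                                         plan.external_test]))
        np.testing.assert_array_equal(allidx, np.arange(200))

    def test_batch_ending_mid_spray_rejected(self):
        b = _batch(100)
        b.phase[:] = "spray"
        with pytest.raises(ValueError, match="drying"):
            ma1add_split(b)


class TestFoldsAndPlans:
    def test_block_plan_sizes(self):
        plan = block_cv_plan(100, 10)
        assert np.all(np.bincount(plan.folds) == 10)

    def test_ma2a_trios(self):
        c, _ = simulate_campaign(SimConfig(n_batches=12, rows_per_batch=(30, 40), seed=0))
        folds = ma2_folds(c, 9, 3)
        assert len(folds) == 4
        tested = [bid for _, test in folds for bid in test]
        assert tested == c.batch_ids  # partition, order preserved

    def test_ma2b_is_leave_one_batch_out(self):
        c, _ = simulate_campaign(SimConfig(n_batches=12, rows_per_batch=(30, 40), seed=0))
        folds = ma2_folds(c, 11, 1)
        assert len(folds) == 12
        assert all(len(test) == 1 and len(train) == 11 for train, test in folds)

    def test_indivisible_grouping_rejected(self):
        c, _ = simulate_campaign(SimConfig(n_batches=10, rows_per_batch=(30, 40), seed=0))
        with pytest.raises(ValueError, match="residue"):
            ma2_folds(c, 7, 3)


class TestPredictorMatrix:
    def test_merged_has_273_columns(self):
        b = _batch(60)
        assert predictor_matrix(b, "merged").shape[1] == 273
        assert predictor_matrix(b, "nir").shape[1] == 256
        assert predictor_matrix(b, "pars").shape[1] == 17

    def test_spray_rate_option_appends_moving_average(self):
        cfg = SimConfig(n_batches=1, rows_per_batch=(60, 60), seed=3,
                        include_spray_rate=True)
        b, _ = simulate_batch(cfg, "t", 3)
        X = predictor_matrix(b, "merged", use_spray_rate=True)
        assert X.shape[1] == 274
        from granupls.preprocess import moving_average
        np.testing.assert_allclose(
            X[:, -1], moving_average(b.params[:, len(PARAMETER_NAMES)], 7))


class TestPairedTest:
    def test_identical_vectors_give_half(self):
        assert paired_test(np.ones(5), np.ones(5)) == 0.5

    def test_uniformly_lower_approaches_zero(self):
        rng = np.random.default_rng(0)
        a = np.full(10, 1.0) + 0.01 * rng.normal(size=10)
        b = a + 50.0 + 0.1 * rng.normal(size=10)
        assert paired_test(a, b) < 1e-6

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(size=8)
        b = a + rng.normal(0.5, 1.0, size=8)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(8))
        from scipy import stats
        assert paired_test(a, b) == pytest.approx(stats.t.cdf(t, df=7))

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_test(np.arange(5.0), np.arange(5.0) + 2.0)


class TestImportance:
    def test_single_model_is_its_own_table(self, rng):
        X = rng.normal(size=(50, 273))
        y = X[:, 260] + 0.1 * rng.normal(size=50)
        m = fit_pls(X, y, 3)
        imp = coefficient_importance([m])
        np.testing.assert_allclose(imp["mean_abs"], np.abs(m.B * m.scaling.sd))
        assert len(imp["parameter_ranking"]) == 17

    def test_margin_is_mean_plus_two_sd(self, rng):
        X = rng.normal(size=(40, 273))
        y = rng.normal(size=40)
        models = [fit_pls(X, y, k) for k in (2, 3)]
        imp = coefficient_importance(models)
        assert imp["margin"] == pytest.approx(
            imp["spectral_mean"] + 2 * imp["spectral_sd"])

    def test_ranking_stable_under_model_order(self, rng):
        X = rng.normal(size=(40, 273))
        y = rng.normal(size=40)
        models = [fit_pls(X, y, k) for k in (2, 3, 4)]
        r1 = coefficient_importance(models)["parameter_ranking"]
        r2 = coefficient_importance(models[::-1])["parameter_ranking"]
        assert [n for n, _ in r1] == [n for n, _ in r2]
        np.testing.assert_allclose([v for _, v in r1], [v for _, v in r2],
                                   rtol=1e-12)


class TestLODHoldout:
    def test_one_fifth_sequential_split(self):
        c, _ = simulate_campaign(
            SimConfig(n_batches=5, rows_per_batch=(80, 120), seed=5,
                      lod_points_per_batch=30))
        rep = lod_holdout(c)
        assert rep["n_train"] == 120 and rep["n_test"] == 30
        assert set(rep["test_index"]) == set(range(4, 150, 5))
        assert rep["rmsep"] > 0

    def test_ten_rows_gives_8_2(self):
        c, _ = simulate_campaign(
            SimConfig(n_batches=1, rows_per_batch=(60, 80), seed=6,
                      lod_points_per_batch=10))
        rep = lod_holdout(c, cv_k=4, max_lv=3)
        assert rep["n_train"] == 8 and rep["n_test"] == 2


class TestRunComparison:
    @pytest.fixture(scope="class")
    def report(self):
        c, _ = simulate_campaign(SimConfig(n_batches=4, rows_per_batch=(100, 140), seed=17))
        return run_comparison(c, "ma1", ("nir", "pars", "merged"), ("dv50",))

    def test_every_unit_has_metrics(self, report):
        for pset in ("nir", "pars", "merged"):
            assert len(report.results["dv50"][pset]) == 4
            for r in report.results["dv50"][pset].values():
                assert r["external"].rmsep > 0
                assert r["external"].rpd is not None

    def test_reference_stats_consistency(self, report):
        ref = report.reference["dv50"]
        assert ref.range == pytest.approx(ref.max - ref.min)
        for r in report.results["dv50"]["nir"].values():
            m = r["external"]
            assert m.rpd * m.rmsep == pytest.approx(ref.sd, rel=1e-12)

    def test_paired_p_computed(self, report):
        assert ("dv50", "merged", "nir") in report.paired_p

    def test_unknown_target_rejected(self):
        c, _ = simulate_campaign(SimConfig(n_batches=3, rows_per_batch=(60, 80), seed=1))
        with pytest.raises(ValueError, match="target"):
            run_comparison(c, "ma1", ("nir",), ("dv55",))

    @pytest.mark.parametrize("approach,n_batches,n_units",
                             [("ma1add", 4, 4), ("ma2c", 8, 2)])
    def test_terminal_drying_and_four_batch_fold_schemes(
            self, approach, n_batches, n_units):
        # ma1add holds out the last half of each batch's drying run (one
        # unit per batch); ma2c predicts four whole batches per fold
        # (8 batches -> 2 folds)
        c, _ = simulate_campaign(SimConfig(n_batches=n_batches,
                                           rows_per_batch=(100, 140), seed=29))
        rep = run_comparison(c, approach, ("pars",), ("dv50",), max_lv=5)
        assert len(rep.results["dv50"]["pars"]) == n_units
        for r in rep.results["dv50"]["pars"].values():
            assert r["external"].rmsep > 0
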