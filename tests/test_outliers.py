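"""PCA diagnostics (Kaiser rule, Mahalanobis, SIMCA) and BBE-PLS mechanics.

The seeded campaign-level recovery rates live in the acceptance suite;
here we test the individual operations against small oracles.
"""

import numpy as np
import pytest

from granupls.outliers import (
    OutlierReport,
    PCAModel,
    bbe_pls,
    choose_n_pc,
    fit_pca,
    mahalanobis_pc,
    simca_p,
)
from granupls.simulate import SimConfig, simulate_campaign

BBE_CFG = SimConfig(n_batches=8, rows_per_batch=(100, 140), seed=21)


class TestPCA:
    def test_kaiser_scores_sum_to_n_variables(self, rng):
        X = rng.normal(size=(30, 12))
        m = fit_pca(X)
        assert m.kaiser_scores.sum() == pytest.approx(12.0, abs=1e-10)
        assert m.explained_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_data_scores_near_one(self, rng):
        X = rng.normal(size=(4000, 10))
        m = fit_pca(X)
        assert np.all(np.abs(m.kaiser_scores - 1.0) < 0.15)

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.normal(size=(25, 8)) * 3 + 1
        m = fit_pca(X, scale_all=False)
        Z = m.scores @ m.loadings.T
        np.testing.assert_allclose(Z, X - m.mean, atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(40, 6))
        m = fit_pca(X)
        peaks = np.abs(m.loadings).argmax(axis=0)
        assert np.all(m.loadings[peaks, np.arange(m.loadings.shape[1])] > 0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((1, 5)))


def _model_with_fractions(fracs, n_vars=256):
    fracs = np.asarray(fracs, dtype=float)
    k = fracs.size
    return PCAModel(
        loadings=np.eye(n_vars)[:, :k],
        explained_fraction=fracs,
        scores=np.zeros((3, k)),
        kaiser_scores=n_vars * fracs,
        mean=np.zeros(n_vars),
        sd=np.ones(n_vars),
    )


class TestChooseNPC:
    def test_floor_at_one_when_nothing_passes(self):
        m = _model_with_fractions(np.full(20, 1 / 20 / 256 * 0.5))
        assert choose_n_pc(m) == 1

    def test_single_dominant_component(self):
        fr = np.concatenate([[0.99], np.full(20, 0.01 / 20)])
        assert choose_n_pc(_model_with_fractions(fr)) == 1

    def test_modified_rule_trims_marginal_components(self):
        # a score sequence whose 4th-7th Kaiser scores are 4.77, 3.44,
        # 1.1, 1.03: the plain threshold rule keeps 7 components, the
        # scree-tempered rule stops at the elbow after the 5th
        mid = np.array([0.15, 0.03, 4.77 / 256, 3.44 / 256, 1.1 / 256, 1.03 / 256])
        # geometric tail continuing smoothly below the threshold, so the only
        # genuine scree elbow above it sits after the 5th component
        r = np.exp(-0.16)
        tail = (1.03 / 256) * np.exp(-0.15) * r ** np.arange(30)
        f1 = 1.0 - mid.sum() - tail.sum()
        fr = np.concatenate([[f1], mid, tail])
        m = _model_with_fractions(fr)
        assert choose_n_pc(m, use_scree=False) == 7
        assert choose_n_pc(m) == 5


class TestMahalanobis:
    def test_centroid_row_has_zero_distance(self, rng):
        X = rng.normal(size=(50, 6))
        m = fit_pca(X, scale_all=False)
        d = mahalanobis_pc(m, 3, rows=m.mean[None, :])
        assert d[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_quadratic_form_oracle(self, rng):
        X = rng.normal(size=(60, 8))
        m = fit_pca(X, scale_all=False)
        d = mahalanobis_pc(m, 4)
        T = m.scores[:, :4]
        S = np.cov(T, rowvar=False, ddof=1)
        Sinv = np.linalg.inv(S)
        cen = T - T.mean(axis=0)
        oracle = np.sqrt(np.sum(cen @ Sinv * cen, axis=1))
        np.testing.assert_allclose(d, oracle, atol=1e-10)

    def test_n_pc_bound_enforced(self, rng):
        X = rng.normal(size=(10, 4))
        m = fit_pca(X, scale_all=False)
        with pytest.raises(ValueError):
            mahalanobis_pc(m, 99)


class TestSIMCA:
    def test_candidate_at_reference_mean_gets_half(self, rng):
        ref = rng.chisquare(5, size=200)
        p = simca_p(np.array([ref.mean()]), reference=ref)
        assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_monotone_decreasing_in_distance(self, rng):
        ref = rng.chisquare(5, size=100)
        cand = np.linspace(0, 50, 20)
        p = simca_p(cand, reference=ref)
        assert np.all(np.diff(p) < 0)
        assert p[-1] < 1e-6

    def test_matches_textbook_t_computation(self):
        from scipy import stats
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = 4.2
        t = (x - ref.mean()) / (ref.std(ddof=1) * np.sqrt(1 + 1 / 5))
        expected = stats.t.sf(t, df=4)
        assert simca_p(np.array([x]), reference=ref)[0] == pytest.approx(expected)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            simca_p(np.array([1.0]), reference=np.ones(10))


class TestBBE:
    @pytest.fixture(scope="class")
    def clean_report(self):
        c, _ = simulate_campaign(BBE_CFG)
        return bbe_pls(c)

    def test_alpha_zero_never_eliminates(self):
        c, _ = simulate_campaign(BBE_CFG)
        rep = bbe_pls(c, alpha=0.0)
        assert rep.eliminated_ids == []
        assert len(rep.surviving_ids) == 8

    def test_cycles_record_rmsecv_pair(self, clean_report):
        for cyc in clean_report.cycles:
            assert cyc["rmsecv_before"] >= 0 and cyc["rmsecv_after"] >= 0
            assert 0 <= cyc["p_value"] <= 1
        # eliminated cycles must actually lower the CV error
        for cyc in clean_report.cycles:
            if cyc["eliminated"] is not None:
                assert cyc["rmsecv_after"] <= cyc["rmsecv_before"]

    def test_elimination_invariant_to_batch_order(self):
        c, _ = simulate_campaign(
            SimConfig(n_batches=6, rows_per_batch=(80, 120), seed=33,
                      outlier_ids=("1002",))
        )
        rep1 = bbe_pls(c)
        from granupls.data import Campaign
        reordered = Campaign(list(reversed(c.batches)), c.grid, c.paramset)
        rep2 = bbe_pls(reordered)
        assert set(rep1.eliminated_ids) == set(rep2.eliminated_ids)

    def test_needs_three_batches(self):
        c, _ = simulate_campaign(SimConfig(n_batches=2, rows_per_batch=(60, 80), seed=1))
        with pytest.raises(ValueError):
            bbe_pls(c)
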