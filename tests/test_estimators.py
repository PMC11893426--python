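import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_hset
from mrpipe.estimators import (
    bh_fdr,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    or_ci,
    wald_ratio,
    weighted_median,
    weighted_mode,
)


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        beta, _ = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert beta == 0.0

    def test_first_order_formula(self):
        beta, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_single_snp_degenerates_to_wald(self):
        hset = make_hset([0.1], [0.01], [0.05], [0.02])
        est, het = ivw(hset)
        assert het is None
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_homogeneous_ratios_q_zero_fixed_equals_random(self):
        bx = [0.1, 0.2, 0.05]
        by = [0.03, 0.06, 0.015]  # all ratios exactly 0.3
        hset = make_hset(bx, [0.01] * 3, by, [0.01] * 3)
        est_f, het_f = ivw(hset, "fixed")
        est_r, het_r = ivw(hset, "random")
        assert est_f.beta == pytest.approx(0.3, abs=1e-14)
        assert het_f.Q == pytest.approx(0.0, abs=1e-20)
        assert het_f.pval == pytest.approx(1.0)
        assert est_r.se == est_f.se

    def test_matches_statsmodels_wls_through_origin(self, three_snp_set):
        bx, sx, by, sy = three_snp_set.arrays()
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        est, _ = ivw(three_snp_set, "fixed")
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales the covariance by the residual mean square;
        # undo it to recover the fixed-effects (unscaled) SE
        se_unscaled = fit.bse[0] / np.sqrt(fit.mse_resid)
        assert est.se == pytest.approx(se_unscaled, abs=1e-10)

    def test_equals_weighted_mean_of_wald_ratios(self, five_snp_set):
        bx, sx, by, sy = five_snp_set.arrays()
        w = bx**2 / sy**2
        expected = np.sum(w * (by / bx)) / np.sum(w)
        est, _ = ivw(five_snp_set, "fixed")
        assert est.beta == pytest.approx(expected, abs=1e-10)

    def test_random_effects_inflates_se_under_heterogeneity(self, five_snp_set):
        est_f, het = ivw(five_snp_set, "fixed")
        est_r, _ = ivw(five_snp_set, "random")
        scale = max(1.0, np.sqrt(het.Q / het.df))
        assert est_r.se == pytest.approx(est_f.se * scale, abs=1e-12)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            ivw(make_hset([], [], [], []))


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.02 + 0.4 * bx
        hset = make_hset(bx, [0.01] * 4, by, [0.01] * 4)
        est, pleio, het = egger(hset)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert pleio.egger_intercept == pytest.approx(0.02, abs=1e-12)
        assert het.Q == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_wls_with_intercept(self, five_snp_set):
        bx, sx, by, sy = five_snp_set.arrays()
        X = sm.add_constant(np.abs(bx))
        y = by * np.sign(bx)
        fit = sm.WLS(y, X, weights=1.0 / sy**2).fit()
        est, pleio, _ = egger(five_snp_set)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert pleio.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        # overdispersion scale is max(1, sqrt(mse)); statsmodels always scales
        scale_sm = np.sqrt(fit.mse_resid)
        factor = max(1.0, scale_sm) / scale_sm
        assert est.se == pytest.approx(fit.bse[1] * factor, abs=1e-10)
        assert pleio.intercept_se == pytest.approx(fit.bse[0] * factor, abs=1e-10)

    def test_orientation_invariance_to_sign_flips(self, five_snp_set):
        bx, sx, by, sy = five_snp_set.arrays()
        bx2, by2 = bx.copy(), by.copy()
        bx2[1], by2[1] = -bx2[1], -by2[1]
        est1 = egger(five_snp_set)[0]
        est2 = egger(make_hset(bx2, sx, by2, sy))[0]
        assert est2.beta == pytest.approx(est1.beta, abs=1e-14)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            egger(make_hset([0.1, 0.2], [0.01] * 2, [0.03, 0.06], [0.01] * 2))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        hset = make_hset([1, 1, 1], [0.01] * 3, [0.1, 0.3, 0.8], [0.01] * 3)
        est = weighted_median(hset, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_unequal_weights_interpolation_hand_computed(self):
        # ratios {0.1, 0.3, 0.8} with normalized weights {0.5, 0.25, 0.25}:
        # CDF midpoints 0.25, 0.625, 0.875 → 0.5 sits between the first two:
        # 0.1 + (0.3-0.1)·(0.5-0.25)/(0.625-0.25) = 0.23333...
        sy = np.array([0.01] * 3)
        bx = np.sqrt(np.array([0.5, 0.25, 0.25])) * 0.01  # w = bx²/sy²
        by = np.array([0.1, 0.3, 0.8]) * bx
        est = weighted_median(make_hset(bx, [0.001] * 3, by, sy), n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.1 + 0.2 * 0.25 / 0.375, abs=1e-12)

    def test_equal_weights_odd_n_is_exact_sample_median(self, rng):
        for _ in range(5):
            ratios = rng.normal(0.3, 0.2, size=7)
            bx = np.ones(7)
            est = weighted_median(
                make_hset(bx, [0.01] * 7, ratios, [0.01] * 7), n_boot=10, seed=0)
            assert est.beta == pytest.approx(np.median(ratios), abs=1e-12)

    def test_bootstrap_se_deterministic_under_seed(self, five_snp_set):
        a = weighted_median(five_snp_set, n_boot=200, seed=42)
        b = weighted_median(five_snp_set, n_boot=200, seed=42)
        assert a.se == b.se


class TestWeightedMode:
    def test_identical_ratios(self):
        hset = make_hset([0.1] * 3, [0.01] * 3, [0.025] * 3, [0.01] * 3)
        est = weighted_mode(hset, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.25)

    def test_mode_resists_outliers_unlike_mean(self):
        ratios = np.array([0.28, 0.29, 0.30, 0.30, 0.31, 0.32, 0.30, 2.0, 2.0])
        bx = np.ones(9)
        by = ratios
        hset = make_hset(bx, [0.01] * 9, by, [0.01] * 9)
        est = weighted_mode(hset, n_boot=10, seed=0)
        assert 0.25 < est.beta < 0.35
        assert abs(est.beta - 0.3) < abs(np.mean(ratios) - 0.3)

    def test_deterministic_under_seed(self, five_snp_set):
        a = weighted_mode(five_snp_set, n_boot=100, seed=7)
        b = weighted_mode(five_snp_set, n_boot=100, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestCochranQ:
    def test_homogeneous_q_zero(self):
        hset = make_hset([0.1, 0.2], [0.01] * 2, [0.03, 0.06], [0.01] * 2)
        het = cochran_q(hset, 0.3)
        assert het.Q == pytest.approx(0.0, abs=1e-18)
        assert het.pval == pytest.approx(1.0)

    def test_two_ratio_arithmetic(self):
        # ratios {0,1}, weights bx²/sy² = 1 each, theta 0.5 → Q = 0.5
        hset = make_hset([1.0, 1.0], [0.1] * 2, [0.0, 1.0], [1.0, 1.0])
        assert cochran_q(hset, 0.5).Q == pytest.approx(0.5, abs=1e-14)

    def test_permutation_invariance(self, five_snp_set, rng):
        q1 = cochran_q(five_snp_set, 0.3).Q
        idx = rng.permutation(five_snp_set.nsnp)
        bx, sx, by, sy = five_snp_set.arrays()
        q2 = cochran_q(make_hset(bx[idx], sx[idx], by[idx], sy[idx]), 0.3).Q
        assert q2 == pytest.approx(q1, abs=1e-14)


class TestOrCi:
    def test_headline_reporting_convention(self):
        # exponentiating a log-odds of 1.1979 with SE 0.3238
        orp, lo, hi = or_ci(1.1979, 0.3238)
        assert lo == pytest.approx(1.7564, rel=1e-3)
        assert hi == pytest.approx(6.2502, rel=1e-3)

    def test_null_beta_symmetric_about_one(self):
        orp, lo, hi = or_ci(0.0, 0.5)
        assert orp == 1.0
        assert lo * hi == pytest.approx(1.0, abs=1e-12)

    def test_zero_se_collapses(self):
        orp, lo, hi = or_ci(0.3, 0.0)
        assert lo == orp == hi


def brute_force_bh(pvals):
    """Step-up BH from the definition: q_i = min_{j≥i} (m·p_(j)/j)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvals[i] / rank)
        adj[i] = min(running_min, 1.0)
    return adj


class TestBhFdr:
    def test_single_p(self):
        out = bh_fdr([0.03])
        assert out[0].fdr_p == pytest.approx(0.03)
        assert out[0].tier == "significant"

    def test_stepup_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert [a.fdr_p for a in out] == pytest.approx([0.04] * 4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_and_dominates_raw(self, pvals):
        out = bh_fdr(pvals)
        expected = brute_force_bh(np.array(pvals))
        for a, e, raw in zip(out, expected, pvals):
            assert a.fdr_p == pytest.approx(e, abs=1e-12)
            assert a.fdr_p >= raw - 1e-15

    def test_tier_convention(self):
        # crafted so raw<0.05 but fdr≥0.05 for the middle entries
        out = bh_fdr([0.001, 0.04, 0.045, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9])
        assert out[0].tier == "significant"
        assert out[1].tier == "potential"
        assert out[3].tier == "null"

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestLeaveOneOut:
    def test_three_snps_each_row_is_pair_ivw(self, three_snp_set):
        rows = leave_one_out(three_snp_set)
        assert len(rows) == 3
        ids = three_snp_set.snp_ids
        for row in rows:
            sub = three_snp_set.subset([s for s in ids if s != row.excluded])
            expected, _ = ivw(sub, "random")
            assert row.estimate.beta == pytest.approx(expected.beta, abs=1e-14)

    def test_homogeneous_set_all_equal_full_estimate(self):
        bx = np.array([0.1, 0.2, 0.05, 0.15])
        hset = make_hset(bx, [0.01] * 4, 0.3 * bx, [0.01] * 4)
        full, _ = ivw(hset)
        for row in leave_one_out(hset):
            assert row.estimate.beta == pytest.approx(full.beta, abs=1e-12)
            assert not row.influential

    def test_gross_outlier_flagged(self):
        bx = np.array([0.1, 0.12, 0.15, 0.2, 0.08])
        by = 0.3 * bx
        by[2] += 0.5  # gross pleiotropic outlier
        hset = make_hset(bx, [0.01] * 5, by, [0.01] * 5)
        rows = leave_one_out(hset)
        flagged = [r.excluded for r in rows if r.influential]
        assert flagged == [hset.snp_ids[2]]


class TestRepresentationInvariance:
    def test_all_estimators_invariant_to_snp_sign_flip(self, five_snp_set):
        bx, sx, by, sy = five_snp_set.arrays()
        bx2, by2 = bx.copy(), by.copy()
        bx2[3], by2[3] = -bx2[3], -by2[3]
        flipped = make_hset(bx2, sx, by2, sy)
        assert ivw(flipped)[0].beta == pytest.approx(ivw(five_snp_set)[0].beta, abs=1e-14)
        assert egger(flipped)[0].beta == pytest.approx(
            egger(five_snp_set)[0].beta, abs=1e-14)
        wm1 = weighted_median(five_snp_set, n_boot=50, seed=3)
        wm2 = weighted_median(flipped, n_boot=50, seed=3)
        assert wm2.beta == pytest.approx(wm1.beta, abs=1e-14)
        assert wm2.se == wm1.se
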