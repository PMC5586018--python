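"""Voxel classification and the pooled statistics: Mann-Whitney, logistic
regression, odds ratios, threshold inversion, ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from fmisovox import (
    GridGeometry,
    LogisticFit,
    ROIMask,
    SeparationError,
    TMRMap,
    classify_voxels,
    count_above,
    fit_logistic_irls,
    mann_whitney,
    odds_ratio,
    pool_whole_series,
    roc_auc,
    tmr_at_probability,
    tmr_max,
)
from fmisovox.stats import label_counts

from conftest import make_uniform_table


def _line_setup(n_pri, n_rec, seed=0):
    """A 1-D geometry whose first n_pri voxels are the primary ROI and the
    first n_rec of those the recurrence ROI."""
    geom = GridGeometry((n_pri + 10, 1, 1))
    pri = np.zeros(geom.shape, bool)
    pri[:n_pri] = True
    rec = np.zeros(geom.shape, bool)
    rec[:n_rec] = True
    rng = np.random.default_rng(seed)
    tmr = TMRMap(rng.uniform(0.3, 2.5, size=geom.shape), geom, 1.0)
    return (ROIMask(pri, geom, "primary"), ROIMask(rec, geom, "recurrence"), tmr)


class TestClassifyVoxels:
    def test_patient_one_bookkeeping(self):
        """13,758 primary voxels with 4,410 overlapping the recurrence ROI
        leave 9,348 non-overlap voxels."""
        pri, rec, tmr = _line_setup(13758, 4410)
        table = classify_voxels(pri, rec, tmr, "1")
        assert label_counts(table) == (4410, 9348)

    def test_absent_recurrence_all_non_overlap(self):
        pri, _, tmr = _line_setup(500, 0)
        table = classify_voxels(pri, None, tmr, "n1")
        assert label_counts(table) == (0, 500)

    def test_recurrence_equal_primary_all_overlap(self):
        pri, _, tmr = _line_setup(500, 0)
        table = classify_voxels(pri, pri.copy(), tmr, "r1")
        assert label_counts(table) == (500, 0)

    def test_outside_recurrence_clipped_with_warning(self):
        pri, _, tmr = _line_setup(100, 0)
        rec = np.zeros(pri.geometry.shape, bool)
        rec[90:105] = True  # 5 voxels outside the primary ROI
        rec_mask = ROIMask(rec, pri.geometry, "recurrence")
        with pytest.warns(UserWarning, match="5 recurrence voxels"):
            table = classify_voxels(pri, rec_mask, tmr, "p")
        assert label_counts(table) == (10, 90)

    def test_outside_recurrence_error_policy(self):
        pri, _, tmr = _line_setup(100, 0)
        rec = np.zeros(pri.geometry.shape, bool)
        rec[95:105] = True
        with pytest.raises(ValueError, match="outside"):
            classify_voxels(pri, ROIMask(rec, pri.geometry, "recurrence"),
                            tmr, "p", outside_policy="error")

    def test_table_tmr_matches_map(self):
        pri, rec, tmr = _line_setup(50, 20)
        table = classify_voxels(pri, rec, tmr, "p")
        assert np.allclose(table["tmr"].to_numpy(), tmr.values[:50, 0, 0])


class TestPoolWholeSeries:
    def test_counts_add(self):
        tables = [make_uniform_table(100, 0.3, rng=np.random.default_rng(i))
                  for i in range(3)]
        for i, t in enumerate(tables):
            t["patient_id"] = f"p{i}"
        pooled = pool_whole_series(tables)
        assert len(pooled) == 300
        n1 = sum(label_counts(t)[0] for t in tables)
        assert label_counts(pooled)[0] == n1

    def test_duplicate_patient_rejected(self):
        t = make_uniform_table(10, 0.5)
        with pytest.raises(ValueError, match="duplicate"):
            pool_whole_series([t, t.copy()])

    def test_empty_input(self):
        assert len(pool_whole_series([])) == 0


def enumeration_p_value(a, b):
    """Oracle: exact two-sided rank-sum p by enumerating every relabeling."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n_a)]
    sums = np.asarray(sums)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_disjoint_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_multisets_symmetric(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.u_statistic == pytest.approx(8.0)  # n^2 / 2
        assert res.p_value >= 0.99

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(size=15)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(a + 100, b + 100)
        assert r1.u_statistic == r2.u_statistic
        assert r1.p_value == r2.p_value

    def test_all_identical_warns_p_one(self):
        with pytest.warns(UserWarning, match="vacuous"):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_agrees_with_enumeration(self, seed):
        """The DP-based exact p equals full enumeration, with and without
        ties, for every small two-group input."""
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 7, size=2)
        vals = rng.integers(0, 5, size=n_a + n_b).astype(float)  # heavy ties
        a, b = vals[:n_a], vals[n_a:]
        if np.ptp(vals) == 0:
            a[0] += 1
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(enumeration_p_value(a, b), abs=1e-12)

    def test_asymptotic_agrees_with_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        a = rng.normal(0.2, 1, size=40)
        b = np.round(rng.normal(0, 1, size=35), 1)  # some ties
        res = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "asymptotic"
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_group_summaries(self):
        res = mann_whitney([1.0, 2.0, 3.0], [10.0, 20.0])
        assert res.mean_a == pytest.approx(2.0)
        assert res.se_a == pytest.approx(1.0 / np.sqrt(3))
        assert res.n_a == 3 and res.n_b == 2


class TestLogisticIRLS:
    def test_null_slope_within_three_se(self):
        table = make_uniform_table(10_000, 0.5, rng=np.random.default_rng(12))
        fit = fit_logistic_irls(table)
        assert abs(fit.slope) < 3 * fit.slope_se

    def test_parameter_recovery(self):
        a, b = -3.092, float(np.log(5.18))
        table = make_uniform_table(100_000, None, a=a, b=b,
                                   rng=np.random.default_rng(77))
        fit = fit_logistic_irls(table)
        assert abs(fit.intercept - a) < 3 * fit.intercept_se
        assert abs(fit.slope - b) < 3 * fit.slope_se

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        table = make_uniform_table(5_000, None, a=-2.0, b=1.2,
                                   rng=np.random.default_rng(4))
        fit = fit_logistic_irls(table)
        x = sm.add_constant(table["tmr"].to_numpy())
        ref = sm.Logit((table["label"] == "ovl").astype(float).to_numpy(), x).fit(disp=0)
        params = np.asarray(ref.params)
        assert fit.intercept == pytest.approx(params[0], abs=1e-6)
        assert fit.slope == pytest.approx(params[1], abs=1e-6)
        assert np.allclose(fit.covariance, ref.cov_params(), atol=1e-6)

    def test_complete_separation_raises(self):
        table = pd.DataFrame({
            "patient_id": "p", "i": range(20), "j": 0, "k": 0,
            "tmr": np.concatenate([np.linspace(2.1, 3, 10), np.linspace(0.5, 1.9, 10)]),
            "label": ["ovl"] * 10 + ["non_ovl"] * 10,
        })
        with pytest.raises(SeparationError, match="separation"):
            fit_logistic_irls(table)

    def test_quasi_separation_raises(self):
        table = pd.DataFrame({
            "patient_id": "p", "i": range(7), "j": 0, "k": 0,
            "tmr": [2.0, 2.5, 3.0, 2.0, 1.0, 1.5, 0.5],
            "label": ["ovl"] * 3 + ["non_ovl"] * 4,
        })
        with pytest.raises(SeparationError, match="quasi"):
            fit_logistic_irls(table)

    def test_constant_tmr_rejected(self):
        table = pd.DataFrame({
            "patient_id": "p", "i": range(4), "j": 0, "k": 0,
            "tmr": [1.0] * 4, "label": ["ovl", "non_ovl", "ovl", "non_ovl"],
        })
        with pytest.raises(ValueError, match="constant"):
            fit_logistic_irls(table)

    def test_single_label_rejected(self):
        table = make_uniform_table(100, 1.0)
        with pytest.raises(ValueError, match="both"):
            fit_logistic_irls(table)


class TestOddsRatio:
    def test_zero_slope_gives_unity(self):
        fit = LogisticFit(0.0, 0.0, np.zeros((2, 2)), 1, 2, True)
        assert odds_ratio(fit)[0] == pytest.approx(1.0)

    def test_zero_se_collapses_ci(self):
        fit = LogisticFit(0.0, np.log(2.0), np.zeros((2, 2)), 1, 2, True)
        or_, lo, hi = odds_ratio(fit)
        assert (or_, lo, hi) == pytest.approx((2.0, 2.0, 2.0))

    def test_wald_ci_reproduces_published_interval(self):
        """With slope ln 5.18 and SE 0.0315 the 95% Wald interval is
        4.87-5.51 to two decimals (the published interval back-solves to
        that SE)."""
        cov = np.array([[0.0, 0.0], [0.0, 0.0315**2]])
        fit = LogisticFit(-3.092, float(np.log(5.18)), cov, 1, 2, True)
        or_, lo, hi = odds_ratio(fit)
        assert round(or_, 2) == 5.18
        assert round(lo, 2) == 4.87
        assert round(hi, 2) == 5.51

    def test_nonconverged_rejected(self):
        fit = LogisticFit(0.0, 1.0, np.zeros((2, 2)), 1, 2, False)
        with pytest.raises(ValueError, match="converged"):
            odds_ratio(fit)


class TestTMRAtProbability:
    def test_half_probability_is_ratio(self):
        fit = LogisticFit.from_parameters(-3.0, 1.5)
        t, _, _ = tmr_at_probability(fit, 0.5)
        assert t == pytest.approx(2.0)

    def test_published_anchor_inversion(self):
        """Anchoring the curve at 50% probability = TMR 1.88 with odds ratio
        5.18 per unit TMR puts the 30% point at 1.37 (rounded inputs give
        1.365 exactly)."""
        b = float(np.log(5.18))
        fit = LogisticFit.from_parameters(-1.88 * b, b)
        t, _, _ = tmr_at_probability(fit, 0.3)
        assert t == pytest.approx(1.365, abs=5e-4)
        assert abs(t - 1.37) <= 0.01

    def test_monotone_in_probability(self):
        fit = LogisticFit.from_parameters(-3.092, float(np.log(5.18)))
        ts = [tmr_at_probability(fit, p)[0] for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(ts) > 0)

    def test_delta_method_interval(self):
        table = make_uniform_table(50_000, None, a=-3.092, b=float(np.log(5.18)),
                                   rng=np.random.default_rng(9))
        fit = fit_logistic_irls(table)
        t, lo, hi = tmr_at_probability(fit, 0.5)
        assert lo < t < hi
        assert lo < -fit.intercept / fit.slope < hi

    def test_zero_slope_unidentifiable(self):
        fit = LogisticFit.from_parameters(0.0, 1e-12)
        with pytest.raises(ValueError, match="unidentifiable"):
            tmr_at_probability(fit, 0.5)

    def test_probability_bounds(self):
        fit = LogisticFit.from_parameters(-1.0, 1.0)
        for p in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                tmr_at_probability(fit, p)


def pairwise_auc(ovl, non):
    """Oracle: fraction of (ovl, non) pairs with tmr_ovl > tmr_non, ties 1/2."""
    wins = sum((o > n) + 0.5 * (o == n) for o in ovl for n in non)
    return wins / (len(ovl) * len(non))


def table_from_groups(ovl, non):
    return pd.DataFrame({
        "patient_id": "p", "i": range(len(ovl) + len(non)), "j": 0, "k": 0,
        "tmr": np.concatenate([ovl, non]),
        "label": ["ovl"] * len(ovl) + ["non_ovl"] * len(non),
    })


class TestROC:
    def test_perfect_separation(self):
        roc = roc_auc(table_from_groups([4.0, 5.0, 6.0], [1.0, 2.0, 3.0]))
        assert roc.auc == pytest.approx(1.0)

    def test_identical_distributions(self):
        vals = [1.0, 1.5, 2.0, 2.5]
        roc = roc_auc(table_from_groups(vals, vals))
        assert roc.auc == pytest.approx(0.5)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        ovl = np.round(rng.uniform(0.5, 2.5, size=8), 1)
        non = np.round(rng.uniform(0.5, 2.5, size=12), 1)
        roc = roc_auc(table_from_groups(ovl, non))
        assert roc.auc == pytest.approx(pairwise_auc(ovl, non), abs=1e-12)

    def test_duality_with_mann_whitney(self):
        rng = np.random.default_rng(23)
        ovl = rng.normal(1.2, 0.4, size=40)
        non = np.round(rng.normal(0.9, 0.4, size=60), 1)
        roc = roc_auc(table_from_groups(ovl, non))
        u = mann_whitney(ovl, non).u_statistic
        assert abs(roc.auc - u / (len(ovl) * len(non))) < 1e-12

    def test_curve_monotone(self):
        rng = np.random.default_rng(29)
        roc = roc_auc(table_from_groups(rng.normal(1, 0.3, 30), rng.normal(0.8, 0.3, 30)))
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc(make_uniform_table(50, 0.0))


class TestCountAboveAndTMRMax:
    def test_strict_inequality(self):
        table = table_from_groups([2.0, 1.88], [1.5, 1.0])
        count, frac = count_above(table, 1.88)
        assert count == 1 and frac == pytest.approx(0.25)

    def test_threshold_below_min_is_all(self):
        table = make_uniform_table(200, 0.5)
        count, frac = count_above(table, 0.0)
        assert count == 200 and round(100 * frac, 2) == 100.00

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_above(make_uniform_table(200, 0.5).iloc[:0], 1.0)

    def test_tmr_max_uniform_and_oracle(self):
        geom = GridGeometry((20, 20, 10))
        rng = np.random.default_rng(31)
        vals = rng.uniform(0.2, 3.0, size=geom.shape)
        tmr = TMRMap(vals, geom, 1.0)
        roi = ROIMask(rng.random(geom.shape) < 0.4, geom)
        assert tmr_max(tmr, roi) == pytest.approx(vals[roi.values].max())
        uniform = TMRMap(np.full(geom.shape, 1.3), geom, 1.0)
        assert tmr_max(uniform, roi) == pytest.approx(1.3)

    def test_tmr_max_monotone_in_roi(self):
        geom = GridGeometry((15, 15, 8))
        rng = np.random.default_rng(37)
        tmr = TMRMap(rng.uniform(0, 2, size=geom.shape), geom, 1.0)
        small = rng.random(geom.shape) < 0.2
        big = small | (rng.random(geom.shape) < 0.3)
        assert tmr_max(tmr, ROIMask(big, geom)) >= tmr_max(tmr, ROIMask(small, geom))

    def test_empty_roi_rejected(self):
        geom = GridGeometry((5, 5, 5))
        tmr = TMRMap(np.ones(geom.shape), geom, 1.0)
        with pytest.raises(ValueError, match="empty"):
            tmr_max(tmr, ROIMask(np.zeros(geom.shape, bool), geom))
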