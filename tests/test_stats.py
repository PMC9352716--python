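"""Statistics engine: pooled effect sizes, rank-sum conventions, the
normality gate, ANCOVA calibration, and regression/logistic behavior."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from disorient import published
from disorient.stats import (
    DegenerateDataError,
    SeparationError,
    ancova_adjusted,
    cohens_d_pooled,
    compare_groups,
    f_squared,
    linear_regression_standardized,
    logistic_risk,
    wilcoxon_rank_sum,
)


class TestCohensD:
    def test_published_group_table_rows_reproduce(self):
        # Unsigned pooled-SD d from printed means/SDs, row-specific n.
        for var in published.EFFECT_SIZE_ROWS:
            row = published.row(var)
            d = cohens_d_pooled(row.control.mean, row.control.sd, row.control.n,
                                row.patient.mean, row.patient.sd, row.patient.n)
            assert d == pytest.approx(row.cohens_d, abs=0.01), var

    def test_equal_means_give_zero(self):
        assert cohens_d_pooled(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_degenerate_groups_rejected(self):
        with pytest.raises(DegenerateDataError, match="degenerate"):
            cohens_d_pooled(1.0, 0.0, 10, 2.0, 0.0, 10)

    @settings(derandomize=True, max_examples=50)
    @given(m1=hst.floats(-5, 5), m2=hst.floats(-5, 5),
           s1=hst.floats(0.1, 3), s2=hst.floats(0.1, 3),
           a=hst.floats(0.1, 4), b=hst.floats(-10, 10))
    def test_symmetric_and_affine_invariant(self, m1, m2, s1, s2, a, b):
        d = cohens_d_pooled(m1, s1, 8, m2, s2, 11)
        assert cohens_d_pooled(m2, s2, 11, m1, s1, 8) == pytest.approx(d)
        rescaled = cohens_d_pooled(a * m1 + b, a * s1, 8, a * m2 + b, a * s2, 11)
        assert rescaled == pytest.approx(d, rel=1e-9)


def enumeration_rank_sum(x, y):
    """Independent oracle: exact permutation distribution of the rank-sum
    statistic; two-sided p as the tail mass at least as extreme as observed."""
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * (n - nx) / 2
    hits = total = 0
    for comb in itertools.combinations(range(n), nx):
        w = ranks[list(comb)].sum() - nx * (nx + 1) / 2
        total += 1
        hits += abs(w - mu) >= abs(w_obs - mu) - 1e-12
    return w_obs, hits / total


class TestWilcoxonRankSum:
    def test_complete_separation_bounds(self):
        w, _ = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 0.0
        w, _ = wilcoxon_rank_sum([3, 4], [1, 2])
        assert w == 4.0  # n_x * n_y

    def test_small_sample_against_enumeration(self):
        x, y = [1, 3, 5], [2, 4]
        w, p = wilcoxon_rank_sum(x, y)
        w_ref, p_ref = enumeration_rank_sum(np.array(x, float), np.array(y, float))
        assert w == w_ref
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_identical_samples_rejected(self):
        with pytest.raises(DegenerateDataError, match="identical"):
            wilcoxon_rank_sum([2, 2, 2], [2, 2])

    @settings(derandomize=True, max_examples=100)
    @given(data=hst.data())
    def test_statistic_range_and_antisymmetry(self, data):
        nx = data.draw(hst.integers(2, 5))
        ny = data.draw(hst.integers(2, 5))
        rng = np.random.default_rng(data.draw(hst.integers(0, 2**31)))
        x, y = rng.normal(size=nx), rng.normal(size=ny)
        wx, px = wilcoxon_rank_sum(x, y)
        wy, py = wilcoxon_rank_sum(y, x)
        assert 0 <= wx <= nx * ny
        assert wx + wy == pytest.approx(nx * ny)
        assert px == pytest.approx(py)

    def test_large_tied_samples_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(1, 5, size=28).astype(float)
        w, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert (w, p) == (ref.statistic, ref.pvalue)


class TestCompareGroups:
    def test_normal_samples_take_t_test(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        res = compare_groups(x, y)
        assert res.test_used == "students_t"
        assert res.p_value > 0.2
        assert res.cohens_d == pytest.approx(
            cohens_d_pooled(x.mean(), x.std(ddof=1), 30, y.mean(), y.std(ddof=1), 30)
        )

    def test_zero_inflated_sample_falls_back_to_rank_sum(self):
        # Disorientation scores are mostly exact zeros; the normality gate
        # must route them to the rank-sum test.
        rng = np.random.default_rng(12)
        x = np.where(rng.random(21) < 0.8, 0.0, rng.uniform(0.1, 1.0, 21))
        y = rng.normal(5, 1, 16)
        assert compare_groups(x, y).test_used == "wilcoxon_rank_sum"

    def test_constant_group_is_not_normal(self):
        y = np.r_[np.zeros(15), 0.4]
        res = compare_groups(np.zeros(21) + 0.0, y)
        assert res.test_used == "wilcoxon_rank_sum"


class TestAncova:
    def test_group_effect_df_convention(self):
        rng = np.random.default_rng(3)
        y1 = rng.normal(1.0, 0.2, 21)
        y2 = rng.normal(2.0, 0.2, 15)
        c1, c2 = rng.normal(50, 10, 21), rng.normal(60, 10, 15)
        fit = ancova_adjusted((y1, y2), (c1, c2), transform="inverse")
        assert (fit.df_between, fit.df_within) == (1, 33)  # n - 3 with n = 36
        assert fit.F_statistic > 4
        assert fit.p_value < 0.05

    def test_no_transform_on_symmetric_data_matches_direct_fit(self):
        rng = np.random.default_rng(4)
        y1, y2 = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        c1, c2 = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        a = ancova_adjusted((y1, y2), (c1, c2), transform="none")
        b = ancova_adjusted((1 / (y1 + 10), 1 / (y2 + 10)),
                            (c1, c2), transform="none")
        assert a.df_within == b.df_within
        assert a.transform_applied == "none"

    def test_zero_outcome_under_inverse_rejected(self):
        with pytest.raises(ValueError, match="inverse"):
            ancova_adjusted((np.array([0.0, 1, 2, 3]), np.array([1.0, 2, 3, 4])),
                            (np.zeros(4), np.zeros(4)), transform="inverse")

    def test_type_one_error_calibrated_under_label_shuffles(self):
        # Permuting group labels should reject at ~alpha.
        rng = np.random.default_rng(8)
        n = 36
        y = rng.normal(1, 0.3, n)
        cov = rng.normal(40, 15, n)
        rejections = 0
        n_shuffles = 2000
        for _ in range(n_shuffles):
            grp = rng.permutation(np.r_[np.zeros(21), np.ones(15)]).astype(bool)
            fit = ancova_adjusted((y[~grp], y[grp]), (cov[~grp], cov[grp]))
            rejections += fit.p_value < 0.05
        assert rejections / n_shuffles == pytest.approx(0.05, abs=0.02)


class TestStandardizedRegression:
    def test_perfect_fit_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError, match="perfect fit"):
            linear_regression_standardized(x, 2 * x + 1)

    def test_f_squared_formula(self):
        assert f_squared(0.5) == pytest.approx(1.0)
        assert f_squared(0.0) == 0.0
        with pytest.raises(ValueError):
            f_squared(1.0)

    def test_f_squared_strictly_increasing(self):
        grid = np.linspace(0, 0.95, 50)
        vals = [f_squared(r) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_published_r2_f2_pairings_within_rounding_bands(self):
        for r2, band in published.R2_F2_PAIRS:
            assert round(f_squared(r2), 2) in band

    def test_recovers_standardized_slope(self):
        rng = np.random.default_rng(21)
        n, beta = 2000, 0.5
        x = rng.normal(size=n)
        y = beta * x + np.sqrt(1 - beta**2) * rng.normal(size=n)
        fit = linear_regression_standardized(x, y)
        assert fit.beta_standardized == pytest.approx(beta, abs=0.05)
        assert fit.residuals_normal
        assert fit.f_squared == pytest.approx(
            fit.r_squared / (1 - fit.r_squared))

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateDataError, match="variance"):
            linear_regression_standardized(np.ones(10), np.arange(10.0))


class TestLogisticRisk:
    def test_uninformative_predictor_gives_unit_odds(self):
        fit = logistic_risk(np.ones(10), ["high"] * 5 + ["low"] * 5)
        assert fit.odds_ratio == 1.0

    def test_recovers_unit_log_odds_slope(self):
        rng = np.random.default_rng(22)
        n = 1000
        x = rng.normal(size=n)
        labels = rng.random(n) < 1 / (1 + np.exp(-x))
        fit = logistic_risk(x, labels)
        assert 2.4 <= fit.odds_ratio <= 3.1  # e = 2.718...
        assert fit.n_high + fit.n_low == n

    def test_complete_separation_raises(self):
        x = np.arange(12.0)
        with pytest.raises(SeparationError, match="separat"):
            logistic_risk(x, x > 5.5)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError, match="classes"):
            logistic_risk(np.arange(6.0), ["high"] * 6)
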