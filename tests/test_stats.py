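from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from arborkit import (SummaryStats, chi_square_gof, f_test_variances,
                      mann_whitney_u, pooled_t, pooled_t_from_summary,
                      welch_t_from_summary)

# published (mean, SD, n) triples for arbor coverage area (µm²), total
# length (µm), branch counts, terminal-branch counts and Strahler order
# counts of adhesion-mutant vs control arborisations, with the |t| values
# reported alongside them
SUMMARY_T_CASES = [
    ((47445, 2298, 13), (29616, 3259, 11), 15.67),  # area, Nlg1 null
    ((47445, 2298, 13), (32696, 4565, 8), 9.89),    # area, Nrx null
    ((2251, 140, 13), (1785, 265, 11), 5.51),       # length, Nlg1 null
    ((2251, 140, 13), (1758, 306, 8), 5.07),        # length, Nrx null
    ((84.38, 10.97, 13), (86.00, 14.74, 11), 0.31),  # branch number
    ((84.38, 10.97, 13), (91.88, 23.27, 8), 1.00),
    ((43.31, 5.59, 13), (44.27, 7.56, 11), 0.36),   # terminal branches
    ((43.31, 5.59, 13), (47.00, 11.50, 8), 0.99),
    ((11.62, 1.94, 13), (11.27, 2.15, 11), 0.41),   # number of orders
    ((11.62, 1.94, 13), (11.88, 2.36, 8), 0.27),
    ((44643, 2982, 10), (46518, 3083, 10), 1.38),   # area, VGlut null
    ((1812, 134, 10), (2024, 216, 10), 2.64),       # length, VGlut null
]


class TestPooledT:
    @pytest.mark.parametrize("a, b, expected_abs_t", SUMMARY_T_CASES)
    def test_reproduces_published_t_values(self, a, b, expected_abs_t):
        res = pooled_t_from_summary(SummaryStats(*a), SummaryStats(*b))
        assert abs(res.statistic) == pytest.approx(expected_abs_t, abs=0.02)
        assert res.df == a[2] + b[2] - 2

    def test_identical_summaries(self):
        s = SummaryStats(5.0, 1.0, 10)
        res = pooled_t_from_summary(s, s)
        assert res.statistic == 0.0 and res.p_two_tailed == pytest.approx(1.0)

    def test_matches_scipy_on_raw_samples(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        res = pooled_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_tailed == pytest.approx(ref.pvalue)

    def test_zero_variance_unequal_means_raises(self):
        with pytest.raises(ZeroDivisionError):
            pooled_t_from_summary(SummaryStats(1, 0, 5), SummaryStats(2, 0, 5))


class TestWelchT:
    def test_equal_variances_close_to_pooled(self):
        a, b = SummaryStats(10, 2, 20), SummaryStats(11, 2, 20)
        w = welch_t_from_summary(a, b)
        p = pooled_t_from_summary(a, b)
        assert w.statistic == pytest.approx(p.statistic, rel=0.01)

    def test_climb_speed_summaries(self):
        # cm/s climbing speeds of control vs adhesion-null flies; the
        # printed report transposes df and statistic — the hand value is
        # |t| ≈ 8.0 on ≈ 19 df
        res = welch_t_from_summary(SummaryStats(2.25, 0.19, 10),
                                   SummaryStats(1.60, 0.18, 11))
        assert abs(res.statistic) == pytest.approx(8.03, abs=0.02)
        assert res.df == pytest.approx(18.6, abs=0.5)
        assert res.p_two_tailed < 1e-4

    def test_large_na_limit_is_one_sample_z(self):
        # as n_a → ∞ the statistic approaches (mean_a − mean_b)/(sd_b/√n_b)
        a = SummaryStats(0.0, 1.0, 10_000_000)
        b = SummaryStats(0.5, 1.0, 25)
        res = welch_t_from_summary(a, b)
        assert res.statistic == pytest.approx(-0.5 / (1.0 / 5.0), rel=1e-3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 3, 14)
        res = welch_t_from_summary(SummaryStats.from_sample(x),
                                   SummaryStats.from_sample(y))
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_tailed == pytest.approx(ref.pvalue)


def enumerate_exact_p(x, y):
    """Brute-force oracle: two-tailed p over all group labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = sps.rankdata(pooled)
    ux_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = [ranks[list(idx)].sum() - nx * (nx + 1) / 2
          for idx in combinations(range(len(pooled)), nx)]
    us = np.asarray(us)
    eps = 1e-9
    lo = np.mean(us <= ux_obs + eps)
    hi = np.mean(us >= ux_obs - eps)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]).statistic == 0

    def test_two_vs_two_exact(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_two_tailed == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_u_convention_sums_to_nx_ny(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=9), rng.normal(size=6)
        res = mann_whitney_u(x, y)
        u_less = sps.mannwhitneyu(x, y, alternative="less").statistic
        u_greater = sps.mannwhitneyu(y, x, alternative="less").statistic
        assert res.statistic == pytest.approx(min(u_less, u_greater))

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_p_matches_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 8, size=2)
        # integer-valued data so ties occur regularly
        x = rng.integers(0, 6, nx).astype(float)
        y = rng.integers(0, 6, ny).astype(float)
        res = mann_whitney_u(x, y)
        assert "exact" in res.method
        assert res.p_two_tailed == pytest.approx(enumerate_exact_p(x, y))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=15)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(np.exp(x), np.exp(y))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=60), rng.normal(size=60)
        res = mann_whitney_u(x, y)
        assert "approx" in res.method
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_observed_equals_expected(self):
        assert chi_square_gof([50, 50], [0.5, 0.5]).statistic == 0.0

    def test_hand_computed_value(self):
        # 70 of 83 filopodia punctum-associated vs a conservative 50 %
        res = chi_square_gof([70, 13], [0.5, 0.5])
        assert res.statistic == pytest.approx(39.14, abs=0.01)
        assert res.p_two_tailed < 1e-4

    def test_equals_squared_binomial_z(self):
        k, n = 70, 83
        res = chi_square_gof([k, n - k], [0.5, 0.5])
        p_hat = k / n
        z = (p_hat - 0.5) / np.sqrt(0.25 / n)
        assert res.statistic == pytest.approx(z ** 2)

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError):
            chi_square_gof([1, 2], [1.0, 0.0])


class TestFTest:
    def test_published_diameter_dispersion(self):
        # punctum-diameter SDs 177.8 nm (n=144) vs 87.9 nm (n=177)
        res = f_test_variances(SummaryStats(435.8, 177.8, 144),
                               SummaryStats(319.6, 87.9, 177))
        assert res.statistic == pytest.approx(4.092, abs=0.005)
        assert res.df == (143, 176)
        assert res.p_two_tailed < 1e-4

    def test_equal_sds(self):
        res = f_test_variances(SummaryStats(0, 2, 10), SummaryStats(0, 2, 10))
        assert res.statistic == 1.0 and res.p_two_tailed == pytest.approx(1.0)

    def test_swap_symmetry(self):
        a, b = SummaryStats(0, 3, 12), SummaryStats(0, 2, 15)
        fwd = f_test_variances(a, b)
        rev = f_test_variances(b, a)
        assert fwd.statistic == pytest.approx(1 / rev.statistic)
        assert fwd.p_two_tailed == pytest.approx(rev.p_two_tailed)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            f_test_variances(SummaryStats(0, 1, 5), SummaryStats(0, 0, 5))


class TestTypeIError:
    """Each test holds its nominal size under its null (10⁴ replicates)."""

    N_REP = 10_000

    def test_pooled_t_null(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(self.N_REP, 12))
        y = rng.normal(size=(self.N_REP, 12))
        mx, my = x.mean(1), y.mean(1)
        vx, vy = x.var(1, ddof=1), y.var(1, ddof=1)
        sp2 = (11 * vx + 11 * vy) / 22
        t = (mx - my) / np.sqrt(sp2 * (2 / 12))
        p = 2 * sps.t.sf(np.abs(t), 22)
        # spot-check the vectorised null against the implementation
        ref = pooled_t(x[0], y[0])
        assert ref.p_two_tailed == pytest.approx(p[0])
        assert 0.035 <= np.mean(p < 0.05) <= 0.065

    def test_f_test_null(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(self.N_REP, 15))
        y = rng.normal(size=(self.N_REP, 15))
        f = x.var(1, ddof=1) / y.var(1, ddof=1)
        p = 2 * np.minimum(sps.f.sf(f, 14, 14), sps.f.cdf(f, 14, 14))
        ref = f_test_variances(SummaryStats.from_sample(x[0]),
                               SummaryStats.from_sample(y[0]))
        assert ref.p_two_tailed == pytest.approx(min(p[0], 1.0))
        assert 0.035 <= np.mean(p < 0.05) <= 0.065

    def test_chi_square_null(self):
        rng = np.random.default_rng(12)
        n = 200
        k = rng.binomial(n, 0.5, size=self.N_REP)
        rejections = 0
        stat = (k - n / 2) ** 2 / (n / 2) + ((n - k) - n / 2) ** 2 / (n / 2)
        p = sps.chi2.sf(stat, 1)
        ref = chi_square_gof([int(k[0]), int(n - k[0])], [0.5, 0.5])
        assert ref.p_two_tailed == pytest.approx(p[0])
        rejections = np.mean(p < 0.05)
        assert 0.035 <= rejections <= 0.065

    def test_mann_whitney_null(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = self.N_REP
        for _ in range(n_rep):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            if mann_whitney_u(x, y).p_two_tailed < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065
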