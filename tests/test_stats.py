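import numpy as np
import pytest

from maxillomorph.stats import (
    StatsError,
    anova_oneway,
    chi_square,
    elbow_select,
    iqr_outliers,
    kmeans_1d,
    pearson_r,
    select_elbow_from_curve,
    welch_t,
    wss_curve,
)

import _oracles as oracle


class TestOracleEquivalence:
    """Every statistic must match an independent brute-force textbook
    implementation on randomly drawn small samples."""

    @pytest.mark.parametrize("seed", range(100))
    def test_welch_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 15))
        b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 15))
        r = welch_t(a, b)
        t, df, p = oracle.welch_oracle(a, b)
        assert r.statistic == pytest.approx(t, rel=1e-9)
        assert r.df == pytest.approx(df, rel=1e-9)
        assert r.p_value == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_anova_matches_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        groups = [
            rng.normal(rng.uniform(-3, 3), 1.0, rng.integers(3, 10))
            for _ in range(rng.integers(2, 5))
        ]
        r = anova_oneway(groups)
        F, df, p = oracle.anova_oracle(groups)
        assert r.statistic == pytest.approx(F, rel=1e-9)
        assert r.df == df
        assert r.p_value == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_chi_square_matches_brute_force(self, seed):
        rng = np.random.default_rng(2000 + seed)
        table = rng.integers(1, 40, (rng.integers(2, 4), rng.integers(2, 4)))
        r = chi_square(table)
        stat, df, p = oracle.chi_square_oracle(table)
        assert r.statistic == pytest.approx(stat, rel=1e-9)
        assert r.df == df
        assert r.p_value == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_pearson_matches_brute_force(self, seed):
        rng = np.random.default_rng(3000 + seed)
        x = rng.normal(size=rng.integers(4, 20))
        y = rng.normal(size=x.size) + 0.5 * x
        assert pearson_r(x, y) == pytest.approx(oracle.pearson_oracle(x, y), rel=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_iqr_fences_match_brute_force(self, seed):
        rng = np.random.default_rng(4000 + seed)
        values = rng.normal(scale=rng.uniform(0.5, 5), size=rng.integers(4, 30))
        flags = iqr_outliers(values)
        inner, outer = oracle.iqr_fences_oracle(values)
        assert flags.inner_fences == pytest.approx(inner, rel=1e-9)
        assert flags.outer_fences == pytest.approx(outer, rel=1e-9)
        for v, f in zip(values, flags.flags):
            expect = "none"
            if v < inner[0] or v > inner[1]:
                expect = "normal"
            if v < outer[0] or v > outer[1]:
                expect = "extreme"
            assert f == expect


class TestIqrOutliers:
    def test_far_value_flagged_extreme(self):
        flags = iqr_outliers([1, 2, 3, 4, 100])
        assert flags.flags.tolist() == ["none", "none", "none", "none", "extreme"]

    def test_constant_data_has_no_outliers(self):
        assert all(iqr_outliers([5.0] * 8).flags == "none")

    def test_mild_outlier_is_normal_not_extreme(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        q1, q3 = np.percentile(base, [25, 75])
        mild = q3 + 2.0 * (q3 - q1)
        flags = iqr_outliers(np.append(base, mild))
        assert flags.flags[-1] == "normal"

    def test_too_few_values_rejected(self):
        with pytest.raises(StatsError):
            iqr_outliers([1.0, 2.0, 3.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_flags_invariant_under_affine_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=20)
        a, b = rng.uniform(0.5, 4.0), rng.uniform(-10, 10)
        assert np.array_equal(iqr_outliers(values).flags, iqr_outliers(a * values + b).flags)


class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_equal_variance_equal_n_reduces_to_student(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        r = welch_t(a, b)
        # pooled-variance Student t for equal n and equal variance
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t_student = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert r.statistic == pytest.approx(t_student, rel=1e-12)
        assert r.df == pytest.approx(4.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestAnova:
    def test_identical_groups(self):
        r = anova_oneway([[1.0, 1.0, 1.0], [1.0, 1.0], [1.0, 1.0, 1.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_two_groups_equals_t_squared(self):
        a = np.array([1.0, 2.0, 4.0, 5.0])
        b = np.array([3.0, 6.0, 7.0, 9.0])
        r = anova_oneway([a, b])
        sp2 = ((a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert r.statistic == pytest.approx(t**2, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            anova_oneway([[1.0, 2.0], [3.0]])


class TestChiSquare:
    def test_homogeneous_table(self):
        r = chi_square([[10, 10], [10, 10]])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        r = chi_square([[20, 0], [0, 20]])
        assert r.statistic == pytest.approx(40.0)
        assert r.df == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_2x2_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 30, 4)
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square([[a, b], [c, d]]).statistic == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_square([[5, 0], [7, 0]])

    def test_yates_correction_shrinks_statistic(self):
        plain = chi_square([[12, 5], [6, 14]], yates=False)
        corrected = chi_square([[12, 5], [6, 14]], yates=True)
        assert corrected.statistic < plain.statistic


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(StatsError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKMeans1D:
    def test_two_point_masses(self):
        values = np.array([0.0] * 10 + [100.0] * 10)
        r = kmeans_1d(values, 2, seed=0)
        assert np.allclose(r.centers, [0.0, 100.0])
        assert np.array_equal(r.assignments, np.array([0] * 10 + [1] * 10))
        assert r.wss == pytest.approx(0.0)

    def test_k1_center_is_mean(self):
        values = np.array([1.0, 2.0, 3.0, 10.0])
        r = kmeans_1d(values, 1, seed=0)
        assert r.centers[0] == pytest.approx(values.mean())

    def test_k_equals_distinct_gives_zero_wss(self):
        values = np.array([1.0, 1.0, 5.0, 9.0])
        assert kmeans_1d(values, 3, seed=0).wss == pytest.approx(0.0)

    def test_k_above_distinct_rejected(self):
        with pytest.raises(StatsError):
            kmeans_1d([1.0, 1.0, 2.0], 3, seed=0)

    def test_wss_non_increasing_in_k(self):
        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(8, 1, 30)])
        curve = wss_curve(values, 6, seed=0)
        assert all(curve[i + 1] <= curve[i] + 1e-9 for i in range(len(curve) - 1))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=40)
        a = kmeans_1d(values, 3, seed=5)
        b = kmeans_1d(values, 3, seed=5)
        assert np.array_equal(a.assignments, b.assignments)


class TestElbow:
    def test_two_well_separated_gaussians(self):
        rng = np.random.default_rng(12)
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        assert elbow_select(values, k_max=6, seed=0) == 2

    def test_sex_offset_cohort_selects_two_or_three(self):
        # two-level effect (one subgroup shifted) as in the phantom cohorts
        rng = np.random.default_rng(13)
        values = np.concatenate([rng.normal(-2.0, 0.25, 34), rng.normal(0.0, 0.25, 16)])
        assert elbow_select(values, k_max=6, seed=0) in (2, 3)

    def test_tie_resolves_to_smallest_k(self):
        # linear WSS curve: all second differences are zero
        assert select_elbow_from_curve([4.0, 3.0, 2.0, 1.0, 0.0]) == 2

    def test_k_max_validation(self):
        with pytest.raises(StatsError):
            elbow_select([1.0, 2.0, 3.0, 4.0], k_max=2)

    def test_too_few_distinct_rejected(self):
        with pytest.raises(StatsError):
            elbow_select([1.0, 1.0, 2.0, 2.0], k_max=4)
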