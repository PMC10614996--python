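"""ANOVA, weighted Welch and permutation tests against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from clonewell import (
    CensoredValue,
    bonferroni,
    one_way_anova,
    package_fixture_table2,
    permutation_test_mean,
    permutation_test_mean_exact,
    permutation_test_mean_montecarlo,
    weighted_welch_t_test,
)
from clonewell.stats import count_subsets_sum_leq, permutation_brute_force


class TestAnova:
    def test_hand_computed_example(self):
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(13.5)
        assert (res.df1, res.df2) == (1, 4)

    def test_identical_groups(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=12), rng.normal(0.5, size=9), rng.normal(size=15)]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_group_F_is_squared_pooled_t(self, rng):
        x, y = rng.normal(size=10), rng.normal(0.3, size=14)
        res = one_way_anova([x, y])
        t = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)

    def test_degenerate_inputs(self):
        res = one_way_anova([[2, 2], [2, 2]])
        assert res.extras.get("degenerate")
        res = one_way_anova([[1, 1], [2, 2]])
        assert res.extras.get("infinite_F") and res.p_value == 0.0
        with pytest.raises(ValueError):
            one_way_anova([[1.0]])


class TestWeightedWelch:
    def test_printed_weighted_mean_formula(self):
        res = weighted_welch_t_test([1, 2, 3], [1, 1, 4], [2, 3, 4], [1, 1, 1])
        assert res.extras["mean1"] == pytest.approx(2.5)  # (1+2+12)/6
        assert res.extras["mean2"] == pytest.approx(3.0)

    def test_unit_weights_match_standard_welch(self, rng):
        x, y = rng.normal(size=11), rng.normal(0.4, 2.0, size=7)
        res = weighted_welch_t_test(x, np.ones(11), y, np.ones(7))
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_samples(self):
        res = weighted_welch_t_test([1, 2, 3], [1, 2, 1], [1, 2, 3], [1, 2, 1])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_welch_t_test([1], [1], [1, 2], [1, 1])
        with pytest.raises(ValueError):
            weighted_welch_t_test([1, 2], [1, -1], [1, 2], [1, 1])


class TestExactPermutation:
    def test_table2_reproduces_printed_result(self):
        faster, slower = package_fixture_table2()
        res = permutation_test_mean_exact(faster, slower)
        assert res.extras["mean1"] == pytest.approx(11.4375)
        assert res.extras["count_le"] == 7
        assert res.extras["total_combinations"] == math.comb(64, 32)
        assert res.p_value == pytest.approx(2 * 7 / math.comb(64, 32), rel=1e-12)
        assert res.extras["resolution_invariant"]

    def test_tiny_two_sided_clamp(self):
        res = permutation_test_mean_exact([1], [2])
        assert res.p_value == 1.0

    def test_identical_samples(self):
        res = permutation_test_mean_exact([3, 3, 3], [3, 3, 3])
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_mean_exact([], [1, 2])

    def test_non_integer_routed_to_monte_carlo(self):
        res = permutation_test_mean([1.5, 2.5], [2.0, 3.0], n_perm=200, rng=1)
        assert res.method == "permutation_montecarlo"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=6),
        st.lists(st.integers(0, 20), min_size=1, max_size=6),
    )
    def test_dp_equals_brute_force(self, s1, s2):
        res = permutation_test_mean_exact(s1, s2)
        le, ge, total = permutation_brute_force(s1, s2)
        assert res.extras["count_le"] == le
        assert res.extras["count_ge"] == ge
        assert res.extras["total_combinations"] == total

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 15), min_size=2, max_size=8),
        st.integers(1, 4),
        st.integers(0, 60),
    )
    def test_tail_count_conservation(self, values, m, s):
        """count_le(s) + count_gt(s) = C(n, m) for every threshold."""
        m = min(m, len(values))
        le = count_subsets_sum_leq(values, m, s)
        gt = math.comb(len(values), m) - le
        ge_via_complement = math.comb(len(values), m) - count_subsets_sum_leq(values, m, s - 1)
        assert le + gt == math.comb(len(values), m)
        assert ge_via_complement >= gt

    def test_counts_are_exact_integers(self):
        # C(64,32) exceeds 53-bit float precision; counts must be ints
        faster, slower = package_fixture_table2()
        res = permutation_test_mean_exact(faster, slower)
        assert isinstance(res.extras["count_le"], int)
        assert isinstance(res.extras["total_combinations"], int)
        assert res.extras["total_combinations"] == 1832624140942590534


class TestMonteCarloPermutation:
    def test_identical_samples(self):
        res = permutation_test_mean_montecarlo([1, 2, 3], [1, 2, 3], n_perm=500, rng=0)
        assert res.p_value > 0.5

    def test_table2_below_resolution(self):
        faster, slower = package_fixture_table2()
        n_perm = 2000
        res = permutation_test_mean_montecarlo(faster, slower, n_perm=n_perm, rng=0)
        assert res.p_value <= 2 / (n_perm + 1)

    def test_agrees_with_exact_on_small_instance(self):
        s1, s2 = [1, 2, 8, 9], [5, 6, 7, 10]
        exact = permutation_test_mean_exact(s1, s2)
        n_perm = 20_000
        mc = permutation_test_mean_montecarlo(s1, s2, n_perm=n_perm, rng=3)
        se = math.sqrt(exact.p_value / 2 * (1 - exact.p_value / 2) / n_perm)
        assert mc.p_value == pytest.approx(exact.p_value, abs=6 * se + 2 / n_perm)


class TestCensoredValues:
    def test_resolution(self):
        assert CensoredValue("exact", 11).resolve() == 11
        assert CensoredValue("interval", 16, 20).resolve() == 16
        assert CensoredValue("interval", 16, 20).resolve("maximal") == 20
        assert CensoredValue("right_censored", 20).resolve() == 21

    def test_invalid(self):
        with pytest.raises(ValueError):
            CensoredValue("interval", 5, 3)
        with pytest.raises(ValueError):
            CensoredValue("approximate", 5)


class TestBonferroni:
    def test_printed_threshold_case(self):
        alpha = 2e-4
        assert bonferroni([alpha / 3 - 1e-12], alpha=alpha, m_tests=3) == [True]

    def test_strict_inequality(self):
        assert bonferroni([0.05], alpha=0.05, m_tests=1) == [False]

    def test_zero_always_significant(self):
        assert bonferroni([0.0], alpha=0.05, m_tests=1000) == [True]


def test_anova_type_I_error_calibration():
    """Null rejection rate at alpha=0.05 over 10^4 three-group draws is
    5% +/- 1%."""
    rng = np.random.default_rng(2718)
    n_sim, n = 10_000, 10
    rejections = 0
    for _ in range(n_sim):
        groups = rng.normal(size=(3, n))
        if one_way_anova(groups).p_value < 0.05:
            rejections += 1
    assert 0.04 <= rejections / n_sim <= 0.06
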