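"""Unit and property tests for the statistical kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaedit import stats

from oracles import fisher_two_sided_enumeration


class TestBinomialUpperBound:
    def test_closed_form_at_zero_successes(self):
        # x = 0: U = 1 - alpha**(1/n), exact
        for n in (1, 5, 10, 30, 100, 1000):
            assert stats.binomial_upper_bound(0, n, 0.05) == pytest.approx(
                1 - 0.05 ** (1 / n), abs=1e-12
            )

    def test_all_alternative_reads_bound_is_one(self):
        assert stats.binomial_upper_bound(10, 10, 0.05) == 1.0

    def test_single_read(self):
        assert stats.binomial_upper_bound(0, 1, 0.05) == pytest.approx(0.95)

    def test_defining_tail_equation(self):
        # U solves P(X <= x | p = U) = alpha
        from scipy.stats import binom

        for x, n in [(1, 10), (3, 25), (5, 40)]:
            u = stats.binomial_upper_bound(x, n, 0.05)
            assert binom.cdf(x, n, u) == pytest.approx(0.05, abs=1e-9)

    @pytest.mark.parametrize(
        "x,n,alpha", [(-1, 5, 0.05), (6, 5, 0.05), (0, 0, 0.05), (0, 5, 0.0), (0, 5, 1.0)]
    )
    def test_invalid_inputs_rejected(self, x, n, alpha):
        with pytest.raises((ValueError, TypeError)):
            stats.binomial_upper_bound(x, n, alpha)

    @given(n=st.integers(1, 200), x=st.integers(0, 200))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_x_and_n(self, n, x):
        x = min(x, n)
        u = stats.binomial_upper_bound(x, n)
        if x < n:
            assert stats.binomial_upper_bound(x + 1, n) > u
        assert stats.binomial_upper_bound(x, n + 1) < u or x == n


class TestZeroConfidenceScore:
    def test_printed_reference_values(self):
        # the worked examples of the score definition
        assert stats.zero_confidence_score(0, 5, 0.05) == pytest.approx(3.46, abs=0.01)
        assert stats.zero_confidence_score(0, 10, 0.05) == pytest.approx(5.87, abs=0.01)
        assert stats.zero_confidence_score(0, 30, 0.05) == pytest.approx(10.22, abs=0.01)

    def test_zero_when_all_reads_alternative(self):
        assert stats.zero_confidence_score(5, 5, 0.05) == 0.0

    def test_closed_form_across_depths(self):
        for n in range(1, 1001):
            expected = -10 * math.log10(1 - 0.05 ** (1 / n))
            assert stats.zero_confidence_score(0, n, 0.05) == pytest.approx(expected, abs=1e-9)

    def test_strictly_increasing_in_depth_at_zero_alt(self):
        scores = [stats.zero_confidence_score(0, n) for n in range(1, 200)]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestMinDepthForScore:
    def test_score_ten_cutoff_needs_depth_29(self):
        assert stats.min_depth_for_score(10.0, 0.05) == 29

    def test_matches_scan(self):
        for threshold in (0.1, 1.0, 3.46, 5.87, 10.0, 10.22, 15.0):
            n = stats.min_depth_for_score(threshold, 0.05)
            assert stats.zero_confidence_score(0, n) >= threshold
            if n > 1:
                assert stats.zero_confidence_score(0, n - 1) < threshold

    def test_tiny_threshold_satisfied_at_one_read(self):
        assert stats.min_depth_for_score(0.1, 0.05) == 1


class TestFisherExact:
    def test_balanced_table_p_is_one(self):
        assert stats.fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_perfect_separation(self):
        # 2 of the 11 tables with margins (10,10)/(10,10) are as extreme
        assert stats.fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-12
        )

    def test_matches_enumeration_oracle(self):
        for table in [[3, 1], [1, 3]], [[30, 0], [15, 15]], [[7, 2], [3, 8]]:
            assert stats.fisher_exact_2x2(table) == pytest.approx(
                fisher_two_sided_enumeration(*table[0], *table[1]), abs=1e-12
            )

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2([[0, 0], [0, 0]])

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    @settings(derandomize=True, max_examples=300)
    def test_oracle_equivalence_and_transpose_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = stats.fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d), abs=1e-12)
        assert stats.fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, abs=1e-12)


class TestOddsRatio:
    def test_cross_product(self):
        assert stats.odds_ratio([[10, 2], [3, 15]]) == 25.0

    def test_symmetry(self):
        assert stats.odds_ratio([[5, 5], [5, 5]]) == 1.0

    def test_haldane_correction(self):
        assert stats.odds_ratio([[30, 0], [15, 15]], "haldane") == pytest.approx(61.0)

    def test_zero_cell_semantics(self):
        assert stats.odds_ratio([[30, 0], [15, 15]]) == math.inf
        assert math.isnan(stats.odds_ratio([[30, 0], [15, 0]]))

    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    @settings(derandomize=True, max_examples=200)
    def test_column_swap_inverts(self, a, b, c, d):
        assert stats.odds_ratio([[a, b], [c, d]]) * stats.odds_ratio(
            [[b, a], [d, c]]
        ) == pytest.approx(1.0)


class TestStrandBias:
    def test_balanced_strands_pass(self):
        assert stats.strand_bias_p(50, 50, 50, 50) == 1.0
        assert stats.strand_bias_p(4, 4, 4, 4) == 1.0

    def test_one_sided_alternative_reads_fail(self):
        assert stats.strand_bias_p(50, 50, 30, 0) < 0.01

    def test_no_alternative_reads_trivially_unbiased(self):
        assert stats.strand_bias_p(20, 15, 0, 0) == 1.0


class TestWelch:
    def test_identical_groups(self):
        res = stats.welch_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        res = stats.welch_test([0, 0.01, -0.01, 0], [10, 10.01, 9.99, 10])
        assert res.p_value < 1e-6

    def test_undefined_cases(self):
        assert not stats.welch_test([1.0], [1, 2, 3]).defined
        assert not stats.welch_test([1, 1, 1], [2, 2, 2]).defined

    def test_matches_satterthwaite_formula(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        res = stats.welch_test(a, b)
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert res.statistic == pytest.approx((a.mean() - b.mean()) / se)


class TestKmLogrank:
    def test_identical_groups_no_difference(self):
        t = [5, 10, 15, 20, 25] * 2
        e = [True] * 10
        g = ["a"] * 5 + ["b"] * 5
        res = stats.km_logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation(self):
        t = [1.0] * 20 + [10.0] * 20
        e = [True] * 40
        g = ["a"] * 20 + ["b"] * 20
        assert stats.km_logrank(t, e, g).p_value < 1e-3

    def test_km_curve_is_product_limit(self):
        # hand-computed product-limit estimate: events at 1,2 censor at 3
        res = stats.km_logrank([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0],
                               ["a"] * 3 + ["b"] * 3)
        curve = res.curves["a"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(2 / 3 * 1 / 2)

    def test_no_events_undefined(self):
        res = stats.km_logrank([1, 2, 3, 4], [False] * 4, ["a", "a", "b", "b"])
        assert not res.defined

    def test_group_validation(self):
        with pytest.raises(ValueError):
            stats.km_logrank([1, 2], [True, True], ["a", "a"])
        with pytest.raises(ValueError):
            stats.km_logrank([1, -2], [True, True], ["a", "b"])


class TestBonferroni:
    def test_reference_arithmetic(self):
        assert stats.bonferroni(2.2e-7, 207) == pytest.approx(4.554e-5)

    def test_capped_and_monotone(self):
        assert stats.bonferroni(0.4, 5) == 1.0
        assert stats.bonferroni(0.001, 10) < stats.bonferroni(0.001, 20)
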