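import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal.contingency import ContingencyTable
from pvsignal.stats import (
    RorResult,
    SignalCriteria,
    analyze_table,
    compute_ror,
    evaluate_signal,
    haldane_adjust,
    pearson_chi2,
    proportion,
    round_half_up,
    two_sample_t_equal_var,
)


def table(a, b, c, d, corrected=False):
    return ContingencyTable("x", 5, "siblings_within_parent", a, b, c, d, corrected)


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(2.345, 2, 2.35), (2.344, 2, 2.34), (0.65, 1, 0.7), (132.995, 2, 133.0), (-2.345, 2, -2.35)],
    )
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


class TestHaldane:
    def test_zero_cell_adds_half_to_all_four(self):
        t = haldane_adjust(table(9, 0, 83, 196))
        assert t.cells() == (9.5, 0.5, 83.5, 196.5)
        assert t.corrected

    def test_two_zero_cells(self):
        t = haldane_adjust(table(9, 0, 0, 3))
        assert t.cells() == (9.5, 0.5, 0.5, 3.5)
        assert t.corrected

    def test_no_zero_cell_unchanged(self):
        t = haldane_adjust(table(2, 3, 4, 5))
        assert t.cells() == (2, 3, 4, 5)
        assert not t.corrected

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            haldane_adjust(table(0, 0, 0, 0))


class TestRor:
    def test_dabigatran(self):
        r = compute_ror(table(20, 19, 14, 43))
        assert round_half_up(r.ror, 2) == 3.23
        assert round_half_up(r.ci_low, 2) == 1.35
        assert round_half_up(r.ci_high, 2) == 7.72

    def test_symmetric_table(self):
        assert compute_ror(table(1, 1, 1, 1)).ror == 1.0

    def test_deferasirox_corrected(self):
        r = compute_ror(haldane_adjust(table(9, 0, 0, 3)))
        assert round_half_up(r.ror, 2) == 133.00
        assert round_half_up(r.ci_low, 2) == 2.19
        assert round_half_up(r.ci_high, 2) == 8082.55
        assert r.n_case_mentions == 9  # pre-correction count

    def test_tacrolimus(self):
        r = compute_ror(table(5, 5, 47, 173))
        assert round_half_up(r.ror, 2) == 3.68
        assert round_half_up(r.ci_low, 2) == 1.02
        assert round_half_up(r.ci_high, 2) == 13.25

    def test_zero_cell_without_haldane_is_error(self):
        with pytest.raises(ValueError, match="haldane"):
            compute_ror(table(9, 0, 83, 196))

    def test_ci_log_symmetry(self):
        r = compute_ror(table(20, 19, 14, 43))
        assert math.isclose(
            math.log(r.ci_high) - math.log(r.ror),
            math.log(r.ror) - math.log(r.ci_low),
            abs_tol=1e-12,
        )

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_reciprocity(self, cells):
        a, b, c, d = cells
        r1 = compute_ror(table(a, b, c, d))
        r2 = compute_ror(table(c, d, a, b))
        assert math.isclose(math.log(r1.ror), -math.log(r2.ror), abs_tol=1e-12)
        assert math.isclose(math.log(r1.ci_low), -math.log(r2.ci_high), abs_tol=1e-12)

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_transposition_invariance(self, cells):
        a, b, c, d = cells
        r1 = compute_ror(table(a, b, c, d))
        r2 = compute_ror(table(a, c, b, d))
        assert math.isclose(r1.ror, r2.ror, rel_tol=1e-12)

    def test_oracle_equivalence_all_small_tables(self):
        # brute-force evaluation of the formulas, independent of the package path
        z = 1.96
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b + c + d == 0:
                continue
            r = compute_ror(haldane_adjust(table(a, b, c, d)))
            aa, bb, cc, dd = (
                (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
                if min(a, b, c, d) == 0
                else (a, b, c, d)
            )
            expected = (aa * dd) / (bb * cc)
            se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
            assert math.isclose(r.ror, expected, rel_tol=1e-12)
            assert math.isclose(r.ci_low, expected * math.exp(-z * se), rel_tol=1e-12)
            assert math.isclose(r.ci_high, expected * math.exp(z * se), rel_tol=1e-12)

    def test_against_statsmodels(self):
        sm_stats = pytest.importorskip("statsmodels.stats.contingency_tables")
        for cells in [(20, 19, 14, 43), (9, 5, 27, 135), (7, 4, 4, 20)]:
            a, b, c, d = cells
            t2 = sm_stats.Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
            r = compute_ror(table(*cells))
            assert math.isclose(r.ror, t2.oddsratio, rel_tol=1e-12)
            lo, hi = t2.oddsratio_confint(0.05)
            # statsmodels uses the exact normal quantile, we pin z = 1.96
            assert math.isclose(r.ci_low, lo, rel_tol=1e-3)
            assert math.isclose(r.ci_high, hi, rel_tol=1e-3)

    def test_ci_coverage_under_null(self):
        # 1,000 simulated tables with fixed group sizes and true OR = 1
        rng = np.random.default_rng(2024)
        n1, n2, p = 150, 450, 0.3
        a = rng.binomial(n1, p, size=1000)
        c = rng.binomial(n2, p, size=1000)
        covered = 0
        for ai, ci in zip(a, c):
            t = haldane_adjust(table(ai, n1 - ai, ci, n2 - ci))
            r = compute_ror(t)
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert 930 <= covered <= 970


class TestSignal:
    CRIT = SignalCriteria()

    def _result(self, ror, ci_low, n_cases):
        return RorResult(
            entity="x", level=5, comparator="s", a=1, b=1, c=1, d=1,
            ror=ror, ci_low=ci_low, ci_high=ci_low * 10, z=1.96,
            corrected=False, n_case_mentions=n_cases,
        )

    def test_signal(self):
        assert evaluate_signal(self._result(3.23, 1.35, 20), self.CRIT)

    def test_ror_below_threshold(self):
        assert not evaluate_signal(self._result(1.80, 1.20, 10), self.CRIT)

    def test_ci_low_not_above_one(self):
        assert not evaluate_signal(self._result(5.00, 0.90, 12), self.CRIT)
        assert not evaluate_signal(self._result(5.00, 1.00, 12), self.CRIT)  # strict

    def test_too_few_cases(self):
        assert not evaluate_signal(self._result(2.50, 1.10, 4), self.CRIT)

    def test_boundary_ror_inclusive(self):
        assert evaluate_signal(self._result(2.0, 1.01, 5), self.CRIT)

    def test_unrounded_comparison(self):
        # 1.9951 rounds to 2.00 but must NOT pass the ror >= 2 gate
        assert not evaluate_signal(self._result(1.9951, 1.5, 10), self.CRIT)

    def test_analyze_table_uses_precorrection_count(self):
        r = analyze_table(table(9, 0, 83, 196), self.CRIT)
        assert r.corrected and r.n_case_mentions == 9 and r.signal


class TestChi2:
    def test_sex_table(self):
        stat, df, p = pearson_chi2([[148, 173], [823, 529]])
        assert round_half_up(stat, 4) == 23.2272
        assert df == 1 and p < 0.001

    def test_hospitalization_table(self):
        stat, df, _ = pearson_chi2([[170, 165], [261, 717]])
        assert round_half_up(stat, 4) == 65.5033

    def test_drugs_per_event_2x5(self):
        stat, df, p = pearson_chi2(
            [[238, 65, 32, 8, 9], [1161, 170, 44, 16, 17]]
        )
        assert round_half_up(stat, 3) == 45.771
        assert df == 4 and p < 0.001

    def test_proportional_rows_give_zero(self):
        stat, _, p = pearson_chi2([[10, 20, 30], [20, 40, 60]])
        assert abs(stat) < 1e-12 and p > 0.999

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[0, 5], [0, 7]])

    @given(st.tuples(*[st.integers(1, 80)] * 4))
    def test_2x2_closed_form_oracle(self, cells):
        a, b, c, d = cells
        stat, df, _ = pearson_chi2([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert df == 1
        assert math.isclose(stat, closed, rel_tol=1e-12)


class TestTTest:
    def test_equal_means_give_zero(self):
        t, df, p = two_sample_t_equal_var(50, 10, 30, 50, 12, 40)
        assert t == pytest.approx(0.0)
        assert df == 68

    def test_pooled_formula_oracle(self):
        # independent recomputation of the pooled-variance statistic
        m1, s1, n1, m2, s2, n2 = 59.56, 21.6, 202, 50.00, 22.1, 1087
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        expected = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        t, df, p = two_sample_t_equal_var(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(expected, rel=1e-12)
        assert t == pytest.approx(5.67, abs=0.01)
        assert df == n1 + n2 - 2
        assert p < 0.001

    def test_antisymmetry(self):
        t1, _, _ = two_sample_t_equal_var(60, 5, 20, 50, 6, 25)
        t2, _, _ = two_sample_t_equal_var(50, 6, 25, 60, 5, 20)
        assert t1 == pytest.approx(-t2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sample_t_equal_var(1, 1, 1, 2, 1, 10)
        with pytest.raises(ValueError):
            two_sample_t_equal_var(1, 0, 10, 2, 1, 10)


class TestProportion:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(352, 53505, 0.7), (32, 335, 9.6), (0, 10, 0.0), (114, 352, 32.4), (247, 1408, 17.5)],
    )
    def test_values(self, num, den, expected):
        assert proportion(num, den) == expected

    def test_division_by_zero(self):
        with pytest.raises(ZeroDivisionError):
            proportion(1, 0)

    def test_numerator_bounds(self):
        with pytest.raises(ValueError):
            proportion(11, 10)
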