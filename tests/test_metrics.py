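"""Case-fatality ratios, exact intervals, 2x2 tables, cut-point sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from pneumorisk import (
    build_parameter_table,
    case_fatality_ratio,
    characteristics,
    cutpoint_sweep,
    exact_binomial_ci,
    get_spec,
    recommend_cutpoints,
    two_by_two,
)
from pneumorisk.metrics import LR_INFINITE, LR_OK, LR_UNDEFINED, TwoByTwo
from pneumorisk._util import round_half_away

from conftest import make_record


def pct1(x: float) -> float:
    return round_half_away(100.0 * x, 1)


class TestExactBinomialCi:
    @pytest.mark.parametrize("k,n,est,lo,hi", [
        (20, 917, 2.2, 1.3, 3.3),
        (6, 83, 7.2, 2.7, 15.1),
        (508, 4333, 11.7, 10.8, 12.7),
    ])
    def test_reproduces_published_intervals_at_one_decimal(self, k, n, est, lo, hi):
        p = exact_binomial_ci(k, n)
        assert pct1(p.estimate) == est
        assert pct1(p.ci_low) == lo
        assert pct1(p.ci_high) == hi

    def test_zero_numerator_pins_lower_bound_at_zero(self):
        p = exact_binomial_ci(0, 102)
        assert p.estimate == 0.0 and p.ci_low == 0.0

    def test_full_numerator_pins_upper_bound_at_one(self):
        assert exact_binomial_ci(10, 10).ci_high == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(n=st.integers(1, 500), frac=st.floats(0, 1))
    def test_matches_statsmodels_beta_method(self, n, frac):
        k = min(n, int(frac * (n + 1)))
        p = exact_binomial_ci(k, n)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert p.ci_low == pytest.approx(0.0 if k == 0 else lo, abs=1e-12)
        assert p.ci_high == pytest.approx(1.0 if k == n else hi, abs=1e-12)

    def test_coverage_is_conservative(self):
        """Clopper-Pearson empirical coverage stays >= nominal 95%."""
        rng = np.random.default_rng(7)
        reps = 10_000
        for p_true in (0.02, 0.05, 0.13):
            for n in (100, 900):
                ks = rng.binomial(n, p_true, size=reps)
                covered = 0
                for k, count in zip(*np.unique(ks, return_counts=True)):
                    ci = exact_binomial_ci(int(k), n)
                    if ci.ci_low <= p_true <= ci.ci_high:
                        covered += count
                assert covered / reps >= 0.95


class TestCaseFatalityRatio:
    @pytest.mark.parametrize("deaths,n,expected_pct", [
        (61, 3574, 1.7), (96, 738, 13.0), (869, 17864, 4.9)])
    def test_published_totals(self, deaths, n, expected_pct):
        dead = make_record("d", died=True)
        alive = make_record("a", died=False)
        cfr = case_fatality_ratio([dead] * deaths + [alive] * (n - deaths))
        assert pct1(cfr.estimate) == expected_pct

    def test_all_survivors(self):
        assert case_fatality_ratio([make_record()] * 5).estimate == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            case_fatality_ratio([])


class TestTwoByTwo:
    def test_hand_example(self):
        scores = [3, 4, 1, 2, 3]
        outcomes = [True, True, False, False, False]
        t = two_by_two(scores, outcomes, 3)
        assert (t.tp, t.fn, t.fp, t.tn) == (2, 0, 1, 2)

    def test_cutpoint_below_min_and_above_max(self):
        scores, outcomes = [1, 2], [True, False]
        low = two_by_two(scores, outcomes, 0)
        assert low.fn == low.tn == 0
        high = two_by_two(scores, outcomes, 99)
        assert high.tp == high.fp == 0

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.integers(-2, 17), st.booleans()),
                    min_size=1, max_size=50),
           st.integers(-2, 18))
    def test_agrees_with_brute_force_recount(self, pairs, cut):
        scores = [s for s, _ in pairs]
        outcomes = [o for _, o in pairs]
        t = two_by_two(scores, outcomes, cut)
        assert t.tp == sum(s >= cut and o for s, o in pairs)
        assert t.fp == sum(s >= cut and not o for s, o in pairs)
        assert t.fn == sum(s < cut and o for s, o in pairs)
        assert t.tn == sum(s < cut and not o for s, o in pairs)
        assert t.n_pos == sum(outcomes)


class TestCharacteristics:
    def test_hand_arithmetic(self):
        ch = characteristics(TwoByTwo(tp=45, fp=60, fn=15, tn=40, cutpoint=3))
        assert ch.sensitivity.estimate == 0.75
        assert ch.specificity.estimate == 0.40
        assert ch.lr_pos.value == pytest.approx(1.25)
        assert ch.lr_neg.value == pytest.approx(0.625)
        assert ch.correctly_classified_pct == pytest.approx(100 * 85 / 160)

    def test_perfect_separation(self):
        ch = characteristics(TwoByTwo(tp=5, fp=0, fn=0, tn=5, cutpoint=3))
        assert ch.sensitivity.estimate == 1.0
        assert ch.specificity.estimate == 1.0
        assert ch.lr_neg.value == 0.0
        assert ch.lr_pos.flag == LR_INFINITE

    def test_everyone_positive_at_minimum_cutpoint(self):
        ch = characteristics(TwoByTwo(tp=4, fp=6, fn=0, tn=0, cutpoint=-2))
        assert ch.sensitivity.estimate == 1.0
        assert ch.specificity.estimate == 0.0
        assert ch.lr_pos.value == 1.0 and ch.lr_pos.flag == LR_OK
        assert ch.lr_neg.flag == LR_UNDEFINED

    def test_lr_log_variance_interval(self):
        # SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn))
        ch = characteristics(TwoByTwo(tp=45, fp=60, fn=15, tn=40, cutpoint=3))
        se = math.sqrt(1 / 45 - 1 / 60 + 1 / 60 - 1 / 100)
        expect = 1.25 * math.exp(1.959963984540054 * se)
        assert ch.lr_pos.ci_high == pytest.approx(expect, rel=1e-9)

    def test_haldane_option_fills_zero_cells(self):
        ch = characteristics(TwoByTwo(tp=5, fp=0, fn=0, tn=5, cutpoint=3),
                             haldane=True)
        assert math.isfinite(ch.lr_pos.value) and ch.lr_pos.value > 0

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            characteristics(TwoByTwo(tp=0, fp=3, fn=0, tn=2, cutpoint=1))


class TestCutpointSweep:
    def test_brute_force_example_rows(self):
        scores = [3, 4, 1, 2, 3]
        outcomes = [True, True, False, False, False]
        table = cutpoint_sweep(scores, outcomes, (1, 4))
        assert [r.cutpoint for r in table.rows] == [1, 2, 3, 4]
        last = table.rows[-1]
        assert last.sensitivity.estimate == 0.5
        assert last.specificity.estimate == 1.0
        assert table.rows[0].sensitivity.estimate == 1.0

    def test_cfr_at_exact_point(self):
        scores = [2, 2, 2, 5]
        outcomes = [True, False, False, False]
        table = cutpoint_sweep(scores, outcomes, (2, 5))
        row2 = table.rows[0]
        assert row2.cfr_at_point.numerator == 1
        assert row2.cfr_at_point.denominator == 3
        assert table.rows[1].cfr_at_point is None  # nobody scores exactly 3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cutpoint_sweep([1, 2], [True, True], (1, 2))

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.tuples(st.integers(-1, 17), st.booleans()),
                    min_size=4, max_size=80))
    def test_monotonicity_and_conserved_margins(self, pairs):
        outcomes = [o for _, o in pairs]
        if all(outcomes) or not any(outcomes):
            pairs[0] = (pairs[0][0], not pairs[0][1])
        scores = [s for s, _ in pairs]
        outcomes = [o for _, o in pairs]
        table = cutpoint_sweep(scores, outcomes, (-1, 17))
        sens = [r.sensitivity.estimate for r in table.rows]
        spec = [r.specificity.estimate for r in table.rows]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))
        n_pos = {r.sensitivity.denominator for r in table.rows}
        n_neg = {r.specificity.denominator for r in table.rows}
        assert n_pos == {sum(outcomes)}
        assert n_neg == {len(outcomes) - sum(outcomes)}


class TestRecommendCutpoints:
    @staticmethod
    def _table_with(sens_spec):
        scores, outcomes = [], []
        # build one synthetic sweep and filter on its own rows
        rows = []
        from pneumorisk.metrics import CutpointRow, CutpointTable, Proportion
        for i, (sn, sp) in enumerate(sens_spec):
            prop = lambda p: Proportion(int(p * 1000), 1000, p, p, p)
            rows.append(CutpointRow(i, None, 50.0, prop(sn), prop(sp),
                                    None, None))
        return CutpointTable("synthetic", rows)

    def test_inclusive_band_boundaries(self):
        table = self._table_with([(0.90, 0.10), (0.80, 0.40), (0.60, 0.40),
                                  (0.59, 0.90), (0.751, 0.679)])
        assert recommend_cutpoints(table) == [1, 2, 4]

    def test_all_rows_above_sensitivity_band(self):
        table = self._table_with([(0.95, 0.5), (0.85, 0.6)])
        assert recommend_cutpoints(table) == []


class TestParameterTable:
    def _cohort(self):
        # 10 children: 4 hypoxemic (1 death), 6 with indrawing at SpO2>90
        recs = []
        for i in range(4):
            recs.append(make_record(f"h{i}", 6.0, died=(i == 0), spo2=85.0))
        for i in range(6):
            recs.append(make_record(f"n{i}", 6.0, died=False, spo2=95.0,
                                    chest_indrawing=True))
        return recs

    def test_strata_counts_and_cfr(self):
        table = build_parameter_table(self._cohort(),
                                      get_spec("risc_hiv_negative"))
        row = table[table.parameter == "SpO2 <= 90%"].iloc[0]
        assert row.n == 4 and row.deaths == 1
        assert row.cfr_pct == pytest.approx(25.0)
        ind = table[table.parameter.str.startswith("Chest indrawing")].iloc[0]
        assert ind.n == 6 and ind.pct == pytest.approx(60.0)
        total = table[table.parameter == "Total"].iloc[0]
        assert total.n == 10 and total.deaths == 1

    def test_strata_not_mutually_exclusive(self):
        recs = [make_record("x", 6.0, died=False, spo2=85.0, wheeze=True,
                            refusal_to_feed=True, waz=-3.5)]
        recs.append(make_record("y", 6.0, died=False))
        table = build_parameter_table(recs, get_spec("risc_hiv_negative"))
        flagged = table[table.parameter != "Total"]
        assert (flagged.n > 0).sum() >= 4  # one child fills several rows

    def test_survivor_only_cohort_has_zero_cfrs(self):
        recs = [make_record(f"p{i}", 6.0, spo2=85.0) for i in range(5)]
        table = build_parameter_table(recs, get_spec("risc_hiv_negative"))
        assert (table[table.n > 0].cfr_pct == 0).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_parameter_table([], get_spec("risc_hiv_negative"))
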