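"""Scoring functions: printed weights, conditional rules, range enumeration."""

import pytest
from hypothesis import given, settings, strategies as st

from pneumorisk import (
    PerchConfig,
    categorize_waz,
    score_perch_adapted,
    score_range,
    score_record,
    score_risc_hiv_negative,
    score_risc_malawi_waz,
)
from pneumorisk.scores import WAZ_MALAWI, WAZ_RISC

from conftest import make_record


class TestWazConventions:
    @pytest.mark.parametrize("waz,convention,expected", [
        (-3.0, WAZ_RISC, "severe"),      # <= -3 is severe under RISC
        (-3.0, WAZ_MALAWI, "moderate"),  # but moderate under RISC-Malawi
        (-2.0, WAZ_RISC, "moderate"),
        (-2.0, WAZ_MALAWI, "normal"),
        (-3.01, WAZ_MALAWI, "severe"),
        (0.0, WAZ_RISC, "normal"),
        (0.0, WAZ_MALAWI, "normal"),
    ])
    def test_band_edges(self, waz, convention, expected):
        assert categorize_waz(waz, convention) == expected

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-10, 10, allow_nan=False),
           st.sampled_from([WAZ_RISC, WAZ_MALAWI]))
    def test_every_finite_waz_maps_to_exactly_one_category(self, waz, conv):
        assert categorize_waz(waz, conv) in {"severe", "moderate", "normal"}

    def test_null_waz_is_callers_error(self):
        with pytest.raises(ValueError):
            categorize_waz(None, WAZ_RISC)


class TestRiscHivNegative:
    @pytest.mark.parametrize("kw,expected", [
        # hypoxemic, indrawing ignored, refusing feeds, severely underweight
        (dict(spo2=85, chest_indrawing=True, wheeze=False,
              refusal_to_feed=True, waz=-3.5), 6),
        # wheezer with no other findings: the score minimum
        (dict(spo2=95, chest_indrawing=False, wheeze=True,
              refusal_to_feed=False, waz=0.0), -2),
        # indrawing counts because SpO2 > 90
        (dict(spo2=95, chest_indrawing=True, wheeze=True,
              refusal_to_feed=False, waz=-2.5), 1),
    ])
    def test_printed_weight_sums(self, kw, expected):
        assert score_risc_hiv_negative(make_record(**kw)).total == expected

    @settings(max_examples=150, derandomize=True)
    @given(spo2=st.floats(50, 100, allow_nan=False), wheeze=st.booleans(),
           refusal=st.booleans(), waz=st.floats(-5, 2, allow_nan=False))
    def test_conditional_indrawing_rule(self, spo2, wheeze, refusal, waz):
        """Toggling indrawing changes nothing at SpO2<=90, exactly 2 above."""
        totals = [
            score_risc_hiv_negative(make_record(
                spo2=spo2, chest_indrawing=ind, wheeze=wheeze,
                refusal_to_feed=refusal, waz=waz)).total
            for ind in (True, False)]
        if spo2 <= 90:
            assert totals[0] == totals[1]
        else:
            assert totals[0] - totals[1] == 2

    def test_null_required_field_names_it(self):
        rec = make_record()
        rec.spo2 = None
        with pytest.raises(ValueError, match="spo2"):
            score_risc_hiv_negative(rec)


class TestRiscMalawi:
    @pytest.mark.parametrize("kw,expected", [
        (dict(spo2=88, waz=-3.2, sex="female", wheeze=False,
              unconscious=True), 17),   # every adverse stratum: the maximum
        (dict(spo2=95, waz=0.0, sex="male", wheeze=False,
              unconscious=False), 0),   # all zero-weight strata
        (dict(spo2=91, waz=-2.5, sex="female", wheeze=True,
              unconscious=False), 4),   # 1 + 3 + 1 - 1
    ])
    def test_printed_weight_sums(self, kw, expected):
        assert score_risc_malawi_waz(make_record(**kw)).total == expected

    @pytest.mark.parametrize("spo2,points", [
        (93.0, 0), (92.99, 1), (90.0, 1), (89.99, 5)])
    def test_spo2_band_edges_on_the_real_line(self, spo2, points):
        result = score_risc_malawi_waz(make_record(spo2=spo2, waz=0.0))
        assert result.components[0][1] == points


class TestPerchAdapted:
    @pytest.mark.parametrize("kw,expected", [
        (dict(age=6, sex="female", cough_history=False, grunting=True,
              spo2=90, illness_duration_days=6, waz=-3.5,
              unconscious=False), 12),  # external-application maximum
        (dict(age=24, sex="male", cough_history=True, grunting=False,
              spo2=95, illness_duration_days=1, waz=0.0,
              unconscious=False), -1),  # minimum: the cough term
        (dict(age=6, sex="female", cough_history=True, grunting=True,
              spo2=90, illness_duration_days=4, waz=-3.5,
              unconscious=False), 11),
    ])
    def test_printed_weight_sums(self, kw, expected):
        assert score_perch_adapted(make_record(**kw)).total == expected

    def test_duration_bands_distinct_labels_equal_weight(self):
        mid = score_perch_adapted(make_record(illness_duration_days=4.0))
        late = score_perch_adapted(make_record(illness_duration_days=9.0))
        (lbl_mid, pts_mid), = [c for c in mid.components if "duration" in c[0]]
        (lbl_late, pts_late), = [c for c in late.components if "duration" in c[0]]
        assert pts_mid == pts_late == 2
        assert lbl_mid != lbl_late

    def test_unconscious_weight_configurable(self):
        rec = make_record(unconscious=True)
        assert (score_perch_adapted(rec, PerchConfig(2)).total
                - score_perch_adapted(rec, PerchConfig(0)).total) == 2

    def test_invalid_unresponsive_weight_rejected(self):
        with pytest.raises(ValueError):
            PerchConfig(unresponsive_weight=1)


class TestRangesAndInvariants:
    @pytest.mark.parametrize("name,expected", [
        ("risc_hiv_negative", (-2, 6)),
        ("risc_malawi_waz", (-1, 17)),
        ("perch_adapted", (-1, 12)),
    ])
    def test_enumerated_ranges_match_published(self, name, expected):
        assert score_range(name) == expected

    def test_perch_range_with_original_unresponsiveness_weight(self):
        assert score_range("perch_adapted", PerchConfig(2)) == (-1, 14)

    @settings(max_examples=100, derandomize=True)
    @given(spo2=st.floats(60, 100, allow_nan=False),
           waz=st.floats(-4.5, 1, allow_nan=False),
           female=st.booleans(), wheeze=st.booleans(), unc=st.booleans(),
           name=st.sampled_from(
               ["risc_hiv_negative", "risc_malawi_waz", "perch_adapted"]))
    def test_total_decomposes_and_stays_in_range(self, spo2, waz, female,
                                                 wheeze, unc, name):
        rec = make_record(spo2=spo2, waz=waz,
                          sex="female" if female else "male",
                          wheeze=wheeze, unconscious=unc)
        res = score_record(rec, name)
        assert res.total == sum(p for _, p in res.components)
        lo, hi = score_range(name)
        assert lo <= res.total <= hi

    def test_score_invariant_to_fields_outside_required_set(self):
        rec = make_record()
        changed = make_record(grunting=True, cough_history=False,
                              illness_duration_days=9.0)
        for name in ("risc_hiv_negative", "risc_malawi_waz"):
            assert (score_record(rec, name).total
                    == score_record(changed, name).total)
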