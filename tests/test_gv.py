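"""Glycemic variability metrics: unit conversion, daily stats, CV, GLI, bands."""

import math

import numpy as np
import pytest

from glycotrial import (
    DomainError,
    classify_readings,
    coefficient_of_variation,
    daily_stats,
    glycemic_lability_index,
    mgdl_to_mmol,
    window_summary,
)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "mgdl,mmol",
        [(0.0, 0.0), (180.182, 10.0), (146.1, 146.1 / 18.0182)],
    )
    def test_values(self, mgdl, mmol):
        assert mgdl_to_mmol(mgdl) == pytest.approx(mmol, rel=1e-12)

    def test_146_is_about_8_1(self):
        assert mgdl_to_mmol(146.1) == pytest.approx(8.1085, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            mgdl_to_mmol(-1.0)


class TestDailyStats:
    def test_two_point_closed_form(self, series_factory):
        s = series_factory([1.0, 5.0], [100.0, 120.0])
        st = daily_stats(s, 1)
        assert st.mean == pytest.approx(110.0)
        # SD of two points is |diff| / sqrt(2)
        assert st.sd == pytest.approx(20.0 / math.sqrt(2), rel=1e-12)
        assert st.sd == pytest.approx(14.142, abs=5e-4)
        assert st.count == 2

    def test_single_reading_sd_absent(self, series_factory):
        st = daily_stats(series_factory([3.0], [150.0]), 1)
        assert (st.mean, st.sd, st.count) == (150.0, None, 1)

    def test_constant_readings_sd_zero(self, series_factory):
        st = daily_stats(series_factory([1, 2, 3], [130.0] * 3), 1)
        assert st.sd == 0.0

    def test_empty_day(self, series_factory):
        st = daily_stats(series_factory([1.0], [100.0]), 2)
        assert (st.mean, st.sd, st.count) == (None, None, 0)

    def test_removing_other_days_leaves_day_stats(self, series_factory):
        full = series_factory([1, 5, 25, 30], [100, 120, 200, 220])
        day1_only = series_factory([1, 5], [100, 120])
        assert daily_stats(full, 1) == daily_stats(day1_only, 1)


class TestCV:
    def test_zero_sd(self):
        assert coefficient_of_variation(0.0, 150.0) == 0.0

    def test_direct_formula(self):
        assert coefficient_of_variation(45.0, 150.0) == pytest.approx(30.0)

    def test_trial_scale(self):
        # group-level values in the observed 28-43 % range
        assert coefficient_of_variation(42.6, 100.0) == pytest.approx(42.6)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            coefficient_of_variation(10.0, 0.0)


class TestGLI:
    def test_hand_worked_example(self, series_factory):
        # 180, 126, 180 mg/dL at hours 0, 4, 8: two pairs of +-2.997 mmol/L
        s = series_factory([0.0, 4.0, 8.0], [180.0, 126.0, 180.0])
        gli = glycemic_lability_index(s, 1)
        term = (54.0 / 18.0182) ** 2 / (2 * 4.0)
        assert gli == pytest.approx(2 * term, rel=1e-12)
        assert gli == pytest.approx(2.2455, abs=5e-4)

    def test_constant_series_zero(self, series_factory):
        s = series_factory([0, 2, 5, 7], [140.0] * 4)
        assert glycemic_lability_index(s, 1) == 0.0

    def test_two_readings_unit_case(self, series_factory):
        # 1 mmol/L apart, 1 h apart: GLI = 1 / ((2-1) * 1)
        s = series_factory([1.0, 2.0], [90.0, 90.0 + 18.0182])
        assert glycemic_lability_index(s, 1) == pytest.approx(1.0, rel=1e-12)

    def test_matches_naive_oracle(self, series_factory, gli_oracle):
        t = [0.0, 1.5, 3.0, 7.5, 11.0, 20.0]
        v = [110.0, 180.0, 95.0, 240.0, 60.0, 130.0]
        s = series_factory(t, v)
        assert glycemic_lability_index(s, 1) == pytest.approx(
            gli_oracle(t, v), rel=1e-12
        )

    def test_long_gap_pairs_excluded_and_n_adjusted(self, series_factory, gli_oracle):
        # 13-h gap between readings 2 and 3 exceeds the 12-h default cutoff
        t = [0.0, 2.0, 15.0, 16.0]
        v = [100.0, 160.0, 200.0, 120.0]
        s = series_factory(t, v)
        got = glycemic_lability_index(s, 1)
        assert got == pytest.approx(gli_oracle(t, v), rel=1e-12)
        # all four readings still participate via the two short-gap pairs
        mm = [x / 18.0182 for x in v]
        expected = (mm[0] - mm[1]) ** 2 / (3 * 2.0) + (mm[2] - mm[3]) ** 2 / (3 * 1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_fewer_than_two_eligible_readings_gives_zero(self, series_factory):
        assert glycemic_lability_index(series_factory([5.0], [200.0]), 1) == 0.0
        sparse = series_factory([0.0, 20.0], [100.0, 200.0])
        assert glycemic_lability_index(sparse, 1) == 0.0  # gap 20 h > 12 h


class TestWindowSummary:
    def test_one_day_window_consistent_with_daily_ops(self, series_factory):
        t = [1.0, 4.0, 9.0, 15.0]
        v = [100.0, 160.0, 120.0, 180.0]
        s = series_factory(t, v)
        summ = window_summary(s, (1, 1))
        st = daily_stats(s, 1)
        assert summ.glu_m == pytest.approx(st.mean)
        assert summ.glu_sd == pytest.approx(st.sd)
        assert summ.gli == pytest.approx(glycemic_lability_index(s, 1))
        assert summ.n_readings == 4

    def test_glu_sd_is_mean_of_daily_sds(self, series_factory):
        s = series_factory([1.0, 2.0, 25.0, 26.0], [90.0, 110.0, 180.0, 220.0])
        summ = window_summary(s, (1, 2))
        sd1 = np.std([90.0, 110.0], ddof=1)
        sd2 = np.std([180.0, 220.0], ddof=1)
        assert summ.glu_sd == pytest.approx((sd1 + sd2) / 2.0)
        assert summ.glu_cv == pytest.approx(summ.glu_sd * 100.0 / summ.glu_m)

    def test_empty_window_absent_statistics(self, series_factory):
        s = series_factory([1.0, 2.0], [100.0, 120.0])
        summ = window_summary(s, (3, 7))
        assert summ.glu_m is None and summ.glu_sd is None and summ.gli is None
        assert summ.n_readings == 0
        # full-stay quantities still present
        assert summ.peak == 120.0
        assert summ.mcg_day1 == pytest.approx(110.0)

    def test_measurement_density_on_trial_like_sampling(self, series_factory):
        # ~5.7 checks/day: readings every ~4.2 h over a week
        t = np.arange(0.5, 7 * 24, 4.2)
        v = np.full(t.size, 140.0)
        summ = window_summary(series_factory(t, v), (1, 7))
        assert summ.n_per_patient_day == pytest.approx(t.size / 7.0)
        assert 5.0 < summ.n_per_patient_day < 6.5

    def test_peak_at_least_mean(self, series_factory):
        s = series_factory([0.5, 3.0, 10.0], [100.0, 300.0, 120.0])
        summ = window_summary(s, (1, 7))
        assert summ.peak >= summ.glu_m


class TestBandClassification:
    def test_all_in_control_band(self, series_factory):
        s = series_factory([1, 2, 3], [120.0] * 3)
        bc = classify_readings(s)
        assert bc.pct_band_80_150 == 100.0
        assert bc.severe_hypo == bc.moderate_hypo == 0
        assert bc.in_target == 3

    def test_edge_convention_enumeration(self, series_factory):
        # <50 severe; [50, 80] moderate; (80, 150] control band
        s = series_factory([1, 2, 3, 4], [49.0, 50.0, 80.0, 81.0])
        bc = classify_readings(s)
        assert (bc.severe_hypo, bc.moderate_hypo, bc.band_80_150) == (1, 2, 1)

    def test_target_band_inclusive(self, series_factory):
        s = series_factory([1, 2, 3, 4], [109.9, 110.0, 150.0, 150.1])
        bc = classify_readings(s)
        assert bc.in_target == 2
        assert bc.above_150 == 1

    def test_empty_series_all_zero(self, series_factory):
        s = series_factory([1.0], [100.0]).day_slice(2)  # empty subset
        bc = classify_readings(s)
        assert bc.n_total == 0
        assert bc.pct_severe is None


def test_cv_identical_in_either_unit(series_factory):
    """CV is unitless: mg/dL and mmol/L readings give the same percentage."""
    v = np.array([95.0, 140.0, 210.0, 180.0])
    cv_mgdl = coefficient_of_variation(np.std(v, ddof=1), np.mean(v))
    vm = v / 18.0182
    cv_mmol = coefficient_of_variation(np.std(vm, ddof=1), np.mean(vm))
    assert cv_mgdl == pytest.approx(cv_mmol, rel=1e-12)
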