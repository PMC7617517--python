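"""Metric engine: closed forms, oracle equivalence, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from luxtrace import (
    BinningSpec,
    PulseSpec,
    ResponseParams,
    SmoothingSpec,
    ThresholdSpec,
    TimeOfDay,
    barroso_metrics,
    bright_dark_period,
    centroid_of_exposure,
    compute_metrics,
    disparity_index,
    dose,
    duration_above_threshold,
    exponential_moving_average,
    frequency_crossing_threshold,
    interdaily_stability,
    intradaily_variability,
    metric_registry,
    midpoint_cumulative_exposure,
    nvrc,
    nvrc_compare,
    nvrd,
    period_above_threshold,
    pulses_above_threshold,
    threshold_for_duration,
    timing_above_threshold,
)

from conftest import make_series

ABOVE250 = ThresholdSpec("above", 250.0)


# ---------------------------------------------------------------------------
# threshold families
# ---------------------------------------------------------------------------


class TestDurationAboveThreshold:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (ThresholdSpec("above", 250), 180.0),
            (ThresholdSpec("below", 250), 180.0),
            (ThresholdSpec("within", 0, 400), 360.0),
        ],
    )
    def test_count_times_epoch(self, spec, expected):
        s = make_series([0, 300, 300, 0, 300, 0])
        assert duration_above_threshold(s, spec).value == expected

    def test_empty_series_raises(self):
        with pytest.raises(ValueError, match="empty"):
            duration_above_threshold(make_series([]), ABOVE250)

    def test_missing_epochs_ignored_and_reported(self):
        s = make_series([300, np.nan, 300, 0])
        res = duration_above_threshold(s, ABOVE250)
        assert res.value == 120.0 and res.missing_fraction == 0.25

    def test_all_missing_is_undefined_not_zero(self):
        res = duration_above_threshold(make_series([np.nan, np.nan]), ABOVE250)
        assert not res.defined and "missing" in res.reason


class TestTimingAboveThreshold:
    def test_mean_clock_time(self):
        s = make_series([0] * 9 + [1000] + [0] + [1000] + [0] * 12, epoch=3600)
        res = timing_above_threshold(s, ABOVE250)
        assert res.value == TimeOfDay.from_string("10:00")

    def test_no_qualifying_epochs_undefined(self):
        res = timing_above_threshold(make_series([0, 0]), ABOVE250)
        assert not res.defined and res.reason == "no qualifying epochs"

    def test_arithmetic_mean_matches_oracle(self):
        rng = np.random.default_rng(5)
        n = 1440
        values = np.where(rng.random(n) < 100 / n, 500.0, 0.0)
        s = make_series(values)
        res = timing_above_threshold(s, ABOVE250, circular=False)
        tods = np.arange(n) * 60.0
        expected = tods[values >= 250].mean()
        assert res.value.seconds == pytest.approx(expected)


class TestPeriodAboveThreshold:
    def test_uninterrupted_run(self):
        s = make_series(np.array([0, 1, 1, 1, 0, 1]) * 300.0)
        assert period_above_threshold(s, ABOVE250).value == 180.0

    def test_interruptions_bridged_and_counted_in_duration(self):
        s = make_series(np.array([0, 1, 1, 1, 0, 1]) * 300.0)
        res = period_above_threshold(s, ABOVE250, max_interrupt=60)
        assert res.value == 300.0  # 5 epochs including the bridged one

    def test_all_qualifying(self):
        s = make_series([300.0] * 7)
        assert period_above_threshold(s, ABOVE250).value == 7 * 60.0


class TestFrequencyCrossing:
    @pytest.mark.parametrize(
        "values, expected", [([0, 300, 0, 300, 0], 4), ([300] * 5, 0), ([0], 0)]
    )
    def test_transition_count(self, values, expected):
        assert frequency_crossing_threshold(make_series(values), ABOVE250).value == expected

    def test_matches_brute_force_on_random_binary(self):
        rng = np.random.default_rng(2)
        values = rng.choice([0.0, 500.0], size=400)
        res = frequency_crossing_threshold(make_series(values), ABOVE250)
        brute = sum(
            (values[i] >= 250) != (values[i - 1] >= 250) for i in range(1, len(values))
        )
        assert res.value == brute

    def test_comparison_bridges_missing(self):
        s = make_series([0, np.nan, 300])
        assert frequency_crossing_threshold(s, ABOVE250).value == 1


class TestThresholdForDuration:
    def test_kth_largest(self):
        s = make_series([10, 100, 1000])
        assert threshold_for_duration(s, 60, "above").value == 1000.0
        assert threshold_for_duration(s, 120, "above").value == 100.0
        assert threshold_for_duration(s, 60, "below").value == 10.0

    def test_duration_beyond_span_raises(self):
        with pytest.raises(ValueError, match="outside the series span"):
            threshold_for_duration(make_series([1, 2]), 600, "above")

    def test_duration_property_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            values = rng.uniform(0, 5000, rng.integers(5, 60))
            s = make_series(values)
            d = float(rng.integers(1, len(values) + 1)) * 60.0
            t = threshold_for_duration(s, d, "above").value
            assert duration_above_threshold(s, ThresholdSpec("above", t)).value >= d
            larger = values[values > t]
            if larger.size:
                next_t = larger.min()
                assert (
                    duration_above_threshold(s, ThresholdSpec("above", next_t)).value < d
                )


# ---------------------------------------------------------------------------
# pulses
# ---------------------------------------------------------------------------


def _pulse_oracle(values, spec: PulseSpec, epoch: float):
    """Independent O(n^2) merge-and-filter pulse detector."""
    q = [bool(v) for v in spec.threshold.apply(np.asarray(values, float)) & ~np.isnan(values)]
    n = len(q)
    runs = []
    i = 0
    while i < n:
        if q[i]:
            j = i
            while j < n and q[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    max_gap = int(spec.max_interrupt // epoch)
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    min_epochs = math.ceil(spec.min_duration / epoch)
    return [(lo, hi) for lo, hi in merged if hi - lo >= min_epochs]


class TestPulses:
    def test_single_block_onset_midpoint_offset(self):
        values = np.zeros(24 * 60)
        values[10 * 60 : 12 * 60] = 1000.0  # 10:00-12:00
        s = make_series(values)
        spec = PulseSpec(ABOVE250, min_duration=1800, max_interrupt=0)
        out = pulses_above_threshold(s, spec)
        assert out["count"].value == 1
        assert out["mean_onset"].value == TimeOfDay.from_string("10:00")
        assert out["mean_midpoint"].value == TimeOfDay.from_string("11:00")
        assert out["mean_offset"].value == TimeOfDay(12 * 3600 - 60)  # start of last epoch
        assert out["total_duration"].value == 7200.0
        assert out["mean_level"].value == 1000.0

    def test_interruption_within_max_merges_blocks(self):
        values = np.zeros(300)
        values[10:40] = 500.0
        values[43:70] = 500.0  # 3-epoch interruption
        s = make_series(values)
        spec = PulseSpec(ABOVE250, min_duration=600, max_interrupt=180)
        out = pulses_above_threshold(s, spec)
        assert out["count"].value == 1
        assert out["total_duration"].value == 60 * 60.0  # span incl. interruption

    def test_all_below_threshold_zero_pulses(self):
        out = pulses_above_threshold(
            make_series(np.zeros(100)), PulseSpec(ABOVE250, 600, 0)
        )
        assert out["count"].value == 0
        assert not out["mean_onset"].defined

    @pytest.mark.parametrize("mode", ["above", "below", "within"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(42)
        spec_thr = (
            ThresholdSpec(mode, 250.0)
            if mode != "within"
            else ThresholdSpec("within", 100.0, 800.0)
        )
        for _ in range(60):
            n = int(rng.integers(10, 200))
            values = rng.uniform(0, 1000, n)
            spec = PulseSpec(
                spec_thr,
                min_duration=float(rng.integers(1, 6)) * 60,
                max_interrupt=float(rng.integers(0, 4)) * 60,
            )
            s = make_series(values)
            expected = _pulse_oracle(values, spec, 60.0)
            out = pulses_above_threshold(s, spec)
            assert out["count"].value == len(expected)
            if expected:
                durations = [(hi - lo) * 60.0 for lo, hi in expected]
                assert out["total_duration"].value == sum(durations)
                assert out["mean_duration"].value == pytest.approx(np.mean(durations))
                onsets = [lo * 60.0 % 86400 for lo, _ in expected]
                assert out["mean_onset"].value.seconds == pytest.approx(np.mean(onsets))


# ---------------------------------------------------------------------------
# brightest / darkest windows
# ---------------------------------------------------------------------------


class TestBrightDarkPeriod:
    def test_plateau_found_exactly(self):
        values = np.zeros(24 * 60)
        values[8 * 60 : 18 * 60] = 1000.0
        s = make_series(values)
        out = bright_dark_period(s, "bright", window=10 * 3600)
        assert out["mean_level"].value == 1000.0
        assert out["onset"].value == TimeOfDay.from_string("08:00")
        assert out["offset"].value == TimeOfDay(18 * 3600 - 60)
        assert out["midpoint"].value == TimeOfDay.from_string("13:00")

    def test_constant_day_tie_resolves_to_first_window(self):
        s = make_series([10.0] * 24, epoch=3600)
        out = bright_dark_period(s, "bright", window=10 * 3600)
        assert out["onset"].value == TimeOfDay(0)

    def test_wrap_across_midnight_matches_circular_brute_force(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 100, 24)
        values[21:] = 5000.0
        values[:3] = 5000.0  # bright block 21:00-03:00
        s = make_series(values, epoch=3600)
        w = 6
        out = bright_dark_period(s, "bright", window=w * 3600, loop=True)
        ext = np.concatenate([values, values[: w - 1]])
        means = [ext[i : i + w].mean() for i in range(24)]
        best = int(np.argmax(means))
        assert out["onset"].value == TimeOfDay(best * 3600)
        assert out["onset"].value == TimeOfDay.from_string("21:00")
        assert out["mean_level"].value == pytest.approx(means[best])

    def test_dark_window_minimises(self):
        values = np.full(24, 1000.0)
        values[2:7] = 0.0
        out = bright_dark_period(make_series(values, epoch=3600), "dark", window=5 * 3600)
        assert out["mean_level"].value == 0.0
        assert out["onset"].value == TimeOfDay(2 * 3600)


# ---------------------------------------------------------------------------
# exposure timing
# ---------------------------------------------------------------------------


class TestCentroidAndMidpoint:
    def test_symmetric_profile_centroid_at_noon(self):
        tod_h = np.arange(24)
        values = np.exp(-((tod_h - 12.0) ** 2) / 8.0) * 1000
        res = centroid_of_exposure(make_series(values, epoch=3600))
        assert res.value.seconds == pytest.approx(12 * 3600)

    def test_single_nonzero_epoch(self):
        values = np.zeros(24)
        values[15] = 800.0
        s = make_series(values, epoch=3600)
        assert centroid_of_exposure(s).value == TimeOfDay.from_string("15:00")
        assert midpoint_cumulative_exposure(s).value == TimeOfDay.from_string("15:00")

    def test_centroid_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 2000, 24 * 60)
        s = make_series(values)
        tods = np.arange(24 * 60) * 60.0
        expected = (tods * values).sum() / values.sum()
        assert centroid_of_exposure(s).value.seconds == pytest.approx(expected)

    def test_all_zero_day_undefined(self):
        assert not centroid_of_exposure(make_series(np.zeros(10))).defined

    def test_midpoint_uniform_day_earliest_geq_rule(self):
        res = midpoint_cumulative_exposure(make_series([10.0] * 24, epoch=3600))
        assert res.value == TimeOfDay.from_string("11:00")  # 12th epoch

    def test_midpoint_matches_cumulative_scan_oracle(self):
        rng = np.random.default_rng(14)
        values = rng.uniform(0, 100, 144)
        s = make_series(values, epoch=600)
        cum = np.cumsum(values)
        idx = int(np.argmax(cum >= cum[-1] / 2))
        assert midpoint_cumulative_exposure(s).value.seconds == idx * 600.0


# ---------------------------------------------------------------------------
# IS / IV
# ---------------------------------------------------------------------------


def _is_oracle(matrix: np.ndarray) -> float:
    """Brute-force IS on a (days x bins-per-day) matrix."""
    n = matrix.size
    p = matrix.shape[1]
    xbar = matrix.mean()
    hourly = matrix.mean(axis=0)
    num = n * ((hourly - xbar) ** 2).sum()
    den = p * ((matrix - xbar) ** 2).sum()
    return num / den


def _iv_oracle(x: np.ndarray) -> float:
    n = x.size
    return (n * (np.diff(x) ** 2).sum()) / ((n - 1) * ((x - x.mean()) ** 2).sum())


class TestInterdailyStability:
    def test_two_identical_days_give_one(self):
        rng = np.random.default_rng(0)
        day = rng.uniform(0, 1000, 24)
        s = make_series(np.tile(day, 2), epoch=3600)
        assert interdaily_stability(s).value == pytest.approx(1.0)

    def test_constant_series_undefined(self):
        res = interdaily_stability(make_series([5.0] * 48, epoch=3600))
        assert not res.defined and res.reason == "zero variance"

    def test_iid_noise_matches_simulation_oracle(self):
        ours, oracle = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            matrix = rng.uniform(0, 1000, (10, 24))
            s = make_series(matrix.ravel(), epoch=3600)
            ours.append(interdaily_stability(s).value)
            oracle.append(_is_oracle(matrix))
        ours, oracle = np.array(ours), np.array(oracle)
        np.testing.assert_allclose(ours, oracle, rtol=1e-12)
        se = oracle.std(ddof=1) / np.sqrt(len(oracle))
        assert abs(ours.mean() - oracle.mean()) <= 3 * se

    def test_bounded_between_zero_and_one(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            s = make_series(rng.uniform(0, 500, 24 * 5), epoch=3600)
            v = interdaily_stability(s).value
            assert 0.0 <= v <= 1.0 + 1e-12


class TestIntradailyVariability:
    def test_alternating_series_is_exactly_four(self):
        s = make_series(np.tile([100.0, 900.0], 24), epoch=3600)
        assert intradaily_variability(s).value == pytest.approx(4.0, abs=0)

    def test_constant_series_undefined(self):
        assert not intradaily_variability(make_series([3.0] * 48, epoch=3600)).defined

    def test_hourly_sinusoid_matches_direct_formula(self):
        hours = np.arange(240)
        values = 500 + 400 * np.sin(2 * np.pi * hours / 24)
        s = make_series(values, epoch=3600)
        assert intradaily_variability(s).value == pytest.approx(
            _iv_oracle(values), rel=1e-12
        )
        assert intradaily_variability(s).value >= 0


# ---------------------------------------------------------------------------
# EMA, disparity, dose
# ---------------------------------------------------------------------------


class TestExponentialMovingAverage:
    def test_constant_input_fixed_point(self):
        s = make_series([42.0] * 30)
        out = exponential_moving_average(s, SmoothingSpec(half_life=600))
        np.testing.assert_allclose(out.values("LIGHT_ema"), 42.0)

    def test_unit_step_reaches_half_after_one_half_life(self):
        half_life = 3600.0
        values = np.concatenate([np.zeros(10), np.ones(120)])
        s = make_series(values)
        out = exponential_moving_average(s, SmoothingSpec(half_life=half_life))
        at = 10 + int(half_life / 60) - 1  # one half-life after the step
        assert out.values("LIGHT_ema")[at] == pytest.approx(0.5, abs=0.01)

    def test_matches_unrolled_recursion_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(0, 1000, 100)
        s = make_series(values)
        out = exponential_moving_average(s, SmoothingSpec(half_life=900))
        lam = 1 - 2 ** (-60 / 900)
        state = values[0]
        expected = [state]
        for v in values[1:]:
            state = lam * v + (1 - lam) * state
            expected.append(state)
        np.testing.assert_allclose(out.values("LIGHT_ema"), expected, rtol=1e-12)

    def test_missing_input_carries_state(self):
        s = make_series([100.0, np.nan, 100.0])
        out = exponential_moving_average(s, SmoothingSpec(half_life=600))
        smoothed = out.values("LIGHT_ema")
        assert np.isnan(smoothed[1]) and smoothed[2] == pytest.approx(100.0)


class TestDisparityAndDose:
    def test_constant_series_zero_disparity(self):
        assert disparity_index(make_series([7.0] * 10)).value == 0.0

    def test_log_ratio_arithmetic(self):
        assert disparity_index(make_series([0.0, math.e - 1])).value == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(10)
        values = rng.uniform(0, 10_000, 250)
        expected = np.abs(np.diff(np.log(values + 1))).mean()
        assert disparity_index(make_series(values)).value == pytest.approx(expected, rel=1e-12)

    def test_dose_lux_hours(self):
        assert dose(make_series([1000.0] * 60)).value == pytest.approx(1000.0)
        assert dose(make_series(np.zeros(10))).value == 0.0


# ---------------------------------------------------------------------------
# Barroso family
# ---------------------------------------------------------------------------


class TestBarroso:
    def test_constant_series(self):
        s = make_series([500.0] * 48, epoch=3600)
        out = barroso_metrics(s)
        assert out["bright_threshold"].value == 500.0
        assert out["dark_threshold"].value == 500.0
        assert out["bright_cluster"].value == 24 * 3600.0  # full day
        assert out["circadian_variation"].value == 0.0

    def test_two_level_day_bright_mean(self):
        values = np.zeros(1440)
        values[:144] = 1000.0  # exactly 10% of the day bright
        out = barroso_metrics(make_series(values))
        assert out["bright_mean_level"].value == 1000.0
        assert out["dark_mean_level"].value == 0.0

    def test_circadian_variation_matches_cv_oracle(self):
        rng = np.random.default_rng(21)
        days = [rng.uniform(100, 1000, 24) for _ in range(5)]
        s = make_series(np.concatenate(days), epoch=3600)
        out = barroso_metrics(s)
        means = [d.mean() for d in days]
        expected = np.std(means, ddof=1) / np.mean(means)
        assert out["circadian_variation"].value == pytest.approx(expected, rel=1e-12)

    def test_single_day_cv_undefined(self):
        out = barroso_metrics(make_series(np.arange(24.0), epoch=3600))
        assert not out["circadian_variation"].defined


# ---------------------------------------------------------------------------
# non-visual responses
# ---------------------------------------------------------------------------


class TestNonVisualResponses:
    def test_zero_light_zero_response(self):
        s = make_series(np.zeros(100), channel="MEDI")
        response, cumulative = nvrd(s)
        np.testing.assert_allclose(response.values("nvRD"), 0.0)
        assert cumulative.value == 0.0

    def test_saturation_far_above_half_max(self):
        s = make_series([1e6] * 240, channel="MEDI")
        response, cumulative = nvrd(s)
        assert response.values("nvRD")[-1] == pytest.approx(1.0, abs=1e-6)
        # cumulative approaches total duration in response-hours
        assert cumulative.value == pytest.approx(240 * 60 / 3600, rel=0.01)

    def test_half_maximum_after_burn_in(self):
        params = ResponseParams(half_max=100.0, history_half_life=600.0)
        s = make_series([100.0] * 500, channel="MEDI")
        response, _ = nvrd(s, params)
        assert response.values("nvRD")[-1] == pytest.approx(0.5, abs=1e-6)

    def test_responses_stay_in_unit_interval(self):
        rng = np.random.default_rng(13)
        s = make_series(rng.uniform(0, 100_000, 1440), channel="MEDI")
        c = nvrc(s).values("nvRC")
        r = nvrd(s)[0].values("nvRD")
        assert np.nanmin(c) >= 0 and np.nanmax(c) <= 1
        assert np.nanmin(r) >= 0 and np.nanmax(r) <= 1

    def test_identical_curves_compare_to_zero(self):
        s = make_series(np.random.default_rng(1).uniform(0, 1000, 144), channel="MEDI")
        c = nvrc(s)
        out = nvrc_compare(c, c)
        assert out["circadian_disturbance"].value == 0.0
        assert out["circadian_bias"].value == 0.0
        assert out["relative_amplitude_error"].value == 0.0

    def test_constant_offset_closed_form(self):
        base = make_series(np.linspace(0.1, 0.6, 100), channel="nvRC", sid="a")
        delta = 0.2
        shifted = base.with_data(base.data + delta)
        out = nvrc_compare(shifted, base)
        assert out["circadian_bias"].value == pytest.approx(delta)
        assert out["circadian_disturbance"].value == pytest.approx(delta)
        assert out["relative_amplitude_error"].value == pytest.approx(0.0, abs=1e-12)

    def test_half_amplitude_reference_gives_rae_one(self):
        tod = np.linspace(0, 2 * np.pi, 200)
        c = make_series(0.5 + 0.4 * np.sin(tod), channel="nvRC")
        ref = make_series(0.5 + 0.2 * np.sin(tod), channel="nvRC")
        assert nvrc_compare(c, ref)["relative_amplitude_error"].value == pytest.approx(1.0)

    def test_disturbance_bounds_bias(self):
        rng = np.random.default_rng(3)
        a = make_series(np.clip(rng.random(200), 0, 1), channel="nvRC")
        b = make_series(np.clip(rng.random(200), 0, 1), channel="nvRC")
        out = nvrc_compare(a, b)
        assert out["circadian_disturbance"].value >= abs(out["circadian_bias"].value)

    def test_mismatched_grids_rejected(self):
        a = make_series(np.zeros(10), channel="nvRC")
        b = make_series(np.zeros(12), channel="nvRC")
        with pytest.raises(ValueError, match="grids"):
            nvrc_compare(a, b)


# ---------------------------------------------------------------------------
# registry, driver, cross-metric invariants
# ---------------------------------------------------------------------------


class TestRegistry:
    def test_family_and_metric_counts(self):
        table = metric_registry()
        assert table["Family"].nunique() == 17
        assert len(table) == 61
        assert not table["Metric"].duplicated().any()

    def test_expected_families_present(self):
        families = set(metric_registry()["Family"])
        for name in [
            "Barroso",
            "Bright-dark period",
            "Centroid of light exposure",
            "Disparity index",
            "Duration above threshold",
            "Exponential moving average",
            "Frequency crossing threshold",
            "Intradaily variability",
            "Interdaily stability",
            "Midpoint of cumulative exposure",
            "nvRC",
            "nvRD",
            "Period above threshold",
            "Pulses above threshold",
            "Threshold for duration",
            "Timing above threshold",
            "Dose",
        ]:
            assert name in families


class TestDriver:
    def test_long_format_row_arithmetic(self):
        days, metrics = 3, ["dose", "centroid", "midpoint_ce"]
        s = make_series(
            np.tile(np.concatenate([np.zeros(8), np.full(10, 500.0), np.zeros(6)]), days),
            epoch=3600,
        )
        table = compute_metrics([s], metrics=metrics)
        assert len(table) == days * len(metrics)
        assert set(table.columns) == {
            "Id", "Day", "Family", "Metric", "Value", "Units", "Params", "MissingFraction",
        }

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metrics"):
            compute_metrics([make_series([1.0] * 4)], metrics=["nope"])


class TestInvariants:
    def test_scale_equivariance_of_threshold_metrics(self):
        rng = np.random.default_rng(30)
        values = rng.uniform(0, 1000, 200)
        for c in (0.5, 3.0, 120.0):
            a, b = make_series(values), make_series(values * c)
            sa, sb = ThresholdSpec("above", 250.0), ThresholdSpec("above", 250.0 * c)
            assert (
                duration_above_threshold(a, sa).value
                == duration_above_threshold(b, sb).value
            )
            assert (
                period_above_threshold(a, sa, 120).value
                == period_above_threshold(b, sb, 120).value
            )
            ta, tb = timing_above_threshold(a, sa), timing_above_threshold(b, sb)
            assert ta.value == tb.value
            pa = pulses_above_threshold(a, PulseSpec(sa, 300, 60))
            pb = pulses_above_threshold(b, PulseSpec(sb, 300, 60))
            assert pa["count"].value == pb["count"].value

    def test_time_shift_equivariance_of_timing_metrics(self):
        rng = np.random.default_rng(31)
        values = np.where(rng.random(1440) < 0.1, 600.0, 0.0)
        shift_s = 2 * 3600
        a = make_series(values, start="2024-01-01 00:00")
        b = make_series(values, start="2024-01-01 02:00")
        # the shifted series wraps past midnight, so equivariance is the
        # circular-mean property
        ta = timing_above_threshold(a, ABOVE250, circular=True).value
        tb = timing_above_threshold(b, ABOVE250, circular=True).value

        def circ_delta(x, y):
            d = (x - y) % 86400
            return min(d, 86400 - d)

        assert circ_delta(tb.seconds, ta.seconds + shift_s) < 1e-6
        ca = centroid_of_exposure(a, circular=True).value
        cb = centroid_of_exposure(b, circular=True).value
        assert circ_delta(cb.seconds, ca.seconds + shift_s) < 1e-6

    @pytest.mark.parametrize(
        "func",
        [
            lambda s: duration_above_threshold(s, ABOVE250),
            lambda s: timing_above_threshold(s, ABOVE250),
            lambda s: centroid_of_exposure(s),
            lambda s: midpoint_cumulative_exposure(s),
            lambda s: interdaily_stability(s, BinningSpec(bin_width=60.0)),
            lambda s: disparity_index(s),
            lambda s: dose(s),
        ],
    )
    def test_all_missing_input_never_a_silent_number(self, func):
        s = make_series([np.nan] * 10)
        res = func(s)
        assert not res.defined and res.reason
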