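import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actigate import (
    CalibrationError,
    DebounceConfig,
    ThresholdPolicy,
    ValidationError,
    adaptive_target,
    calibrate,
    detect_events,
    effective_threshold_series,
    input2output,
)

from conftest import make_session


def oracle_events(values, times, threshold):
    """Independent per-sample strict-comparison oracle.

    Returns (onset, offset) pairs for maximal runs of samples with
    value > threshold, using the same documented offset convention as the
    engine (offset = next sample time; trailing run extends by the median
    inter-sample interval).
    """
    n = len(values)
    tail = float(np.median(np.diff(times))) if n > 1 else 1.0
    runs = []
    i = 0
    while i < n:
        if values[i] > threshold:
            j = i
            while j < n and values[j] > threshold:
                j += 1
            offset = times[j] if j < n else times[n - 1] + tail
            runs.append((float(times[i]), float(offset)))
            i = j
        else:
            i += 1
    return runs


@pytest.mark.parametrize(
    "value,threshold,expected",
    [(1.0, 0.5, True), (0.5, 0.5, False), (-0.1, 0.0, False), (0.5000001, 0.5, True)],
)
def test_activation_is_strict_comparison(value, threshold, expected):
    assert input2output(value, threshold) is expected


class TestAdaptiveTarget:
    POLICY = ThresholdPolicy(calibrated_value=0.7, adaptive_enabled=True)

    def test_constant_window_returns_constant(self):
        for w in (0.0, 0.3, 1.0):
            pol = ThresholdPolicy(calibrated_value=1.0, max_weight=w)
            assert adaptive_target([4.2] * 5, pol) == pytest.approx(4.2)

    def test_weighted_average_of_max_and_mean(self):
        pol = ThresholdPolicy(calibrated_value=1.0, max_weight=0.5)
        assert adaptive_target([0.0, 1.0], pol) == pytest.approx(0.75)

    def test_degenerate_weights(self):
        window = [0.2, 0.9, 0.4]
        assert adaptive_target(window, ThresholdPolicy(1.0, max_weight=1.0)) == pytest.approx(0.9)
        assert adaptive_target(window, ThresholdPolicy(1.0, max_weight=0.0)) == pytest.approx(0.5)

    def test_empty_window_falls_back_to_calibrated(self):
        assert adaptive_target([], self.POLICY) == pytest.approx(0.7)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.floats(0, 1),
    )
    def test_sandwiched_between_window_min_and_max(self, window, w):
        pol = ThresholdPolicy(calibrated_value=1.0, max_weight=w)
        t = adaptive_target(window, pol)
        assert min(window) - 1e-9 <= t <= max(window) + 1e-9


class TestEffectiveThreshold:
    def test_static_policy_gives_constant_series(self):
        pol = ThresholdPolicy(calibrated_value=0.4)
        values = np.random.default_rng(0).normal(size=50)
        times = np.arange(50) / 10.0
        thr = effective_threshold_series(values, times, pol)
        assert np.all(thr == 0.4)

    def test_full_step_reaches_constant_input_at_second_sample(self):
        pol = ThresholdPolicy(calibrated_value=0.4, adaptive_enabled=True, smoothing_alpha=1.0)
        c = 2.0
        thr = effective_threshold_series(np.full(20, c), np.arange(20) / 10.0, pol)
        assert thr[0] == pytest.approx(0.4)
        assert np.allclose(thr[1:], c)

    def test_geometric_convergence_closed_form(self):
        # thr[i] = (1-a)*thr[i-1] + a*c  =>  |thr[i]-c| = (1-a)^i |thr[0]-c|
        alpha, c, v0 = 0.2, 2.0, 0.5
        pol = ThresholdPolicy(calibrated_value=v0, adaptive_enabled=True, smoothing_alpha=alpha)
        n = 60
        thr = effective_threshold_series(np.full(n, c), np.arange(n) / 10.0, pol)
        i = np.arange(n)
        expected = np.abs(v0 - c) * (1 - alpha) ** i
        assert np.max(np.abs(np.abs(thr - c) - expected)) < 1e-9

    def test_convergence_is_monotone_and_activation_ceases(self):
        pol = ThresholdPolicy(calibrated_value=0.1, adaptive_enabled=True, smoothing_alpha=0.3)
        c = 1.0
        n = 200
        values = np.full(n, c)
        times = np.arange(n) / 10.0
        thr = effective_threshold_series(values, times, pol)
        gaps = np.abs(thr - c)
        assert np.all(np.diff(gaps) <= 1e-15)
        active = values > thr
        assert not active[-1]  # threshold caught up; strict inequality fails

    def test_floor_bounds_relaxation(self):
        pol = ThresholdPolicy(
            calibrated_value=0.5, adaptive_enabled=True, smoothing_alpha=0.5, floor=0.2
        )
        thr = effective_threshold_series(np.zeros(100), np.arange(100) / 10.0, pol)
        assert thr.min() >= 0.2 - 1e-12


class TestDetectEvents:
    POL = ThresholdPolicy(calibrated_value=0.5)

    def test_two_runs_read_off_the_comparison(self):
        values = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        times = np.arange(6) / 10.0
        events = detect_events(values, times, self.POL)
        assert [(e.onset_t, e.offset_t) for e in events] == [(0.1, 0.3), (0.4, 0.5)]
        assert all(e.peak_value == 1.0 and e.threshold_at_onset == 0.5 for e in events)

    def test_all_below_threshold_is_empty(self):
        values = np.full(30, 0.2)
        events = detect_events(values, np.arange(30) / 10.0, self.POL)
        assert events == []

    def test_trailing_run_gets_positive_duration(self):
        values = np.array([0.0, 1.0])
        events = detect_events(values, np.array([0.0, 0.1]), self.POL)
        assert len(events) == 1
        assert events[0].offset_t > events[0].onset_t

    def test_matches_oracle_on_random_signals(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 120))
            values = rng.normal(loc=0.4, scale=0.5, size=n)
            times = np.cumsum(rng.uniform(0.01, 0.05, size=n))
            thr = float(rng.uniform(0.05, 0.9))
            events = detect_events(values, times, ThresholdPolicy(calibrated_value=thr))
            assert [(e.onset_t, e.offset_t) for e in events] == oracle_events(values, times, thr)

    def test_hysteresis_holds_through_shallow_dips(self):
        # dips to 0.45: below threshold 0.5 but above release 0.5*(1-0.2)=0.4
        values = np.array([0.0, 0.8, 0.45, 0.8, 0.3, 0.0])
        times = np.arange(6) / 10.0
        no_hyst = detect_events(values, times, self.POL)
        hyst = detect_events(values, times, self.POL, DebounceConfig(hysteresis_fraction=0.2))
        assert len(no_hyst) == 2
        assert len(hyst) == 1
        assert (hyst[0].onset_t, hyst[0].offset_t) == (0.1, 0.4)

    def test_short_events_dropped(self):
        values = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        times = np.arange(8) / 10.0
        events = detect_events(
            values, times, self.POL, DebounceConfig(min_active_seconds=0.25)
        )
        assert len(events) == 1
        assert events[0].onset_t == pytest.approx(0.3)

    def test_short_gaps_merged(self):
        values = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0])
        times = np.arange(9) / 10.0
        events = detect_events(
            values, times, self.POL, DebounceConfig(min_inactive_seconds=0.15)
        )
        # 0.1 s gap merges, 0.3 s gap survives
        assert [(e.onset_t, e.offset_t) for e in events] == [(0.0, 0.5), (0.8, pytest.approx(0.9))]

    def test_events_ordered_and_non_overlapping(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 150))
            values = rng.normal(loc=0.4, scale=0.6, size=n)
            times = np.cumsum(rng.uniform(0.005, 0.05, size=n))
            deb = DebounceConfig(
                hysteresis_fraction=float(rng.uniform(0, 0.5)),
                min_active_seconds=float(rng.uniform(0, 0.1)),
                min_inactive_seconds=float(rng.uniform(0, 0.1)),
            )
            events = detect_events(values, times, self.POL, deb)
            for a, b in zip(events, events[1:]):
                assert a.offset_t <= b.onset_t

    def test_adaptive_threshold_stops_constant_chatter(self):
        pol = ThresholdPolicy(calibrated_value=0.1, adaptive_enabled=True, smoothing_alpha=0.4)
        n = 400
        values = np.full(n, 1.0)
        times = np.arange(n) / 50.0
        events = detect_events(values, times, pol)
        assert len(events) == 1
        assert events[0].offset_t < times[-1]  # activation ceased mid-session


class TestCalibrate:
    def _pair(self, rest_vals, effort_vals):
        rest = make_session(rest_vals, role="rest_calibration")
        effort = make_session(effort_vals, role="effort_calibration")
        return rest, effort

    def test_threshold_halfway_between_rest_and_effort(self):
        rest, effort = self._pair(np.zeros(50), np.ones(50))
        pol = calibrate(rest, effort, fraction=0.5)
        assert pol.calibrated_value == pytest.approx(0.5)

    def test_high_fraction_sits_just_below_effort(self):
        rest, effort = self._pair(np.zeros(50), np.ones(50))
        pol = calibrate(rest, effort, fraction=0.999)
        assert 0.99 < pol.calibrated_value < 1.0

    def test_monotone_in_fraction_and_strictly_inside_band(self, rng):
        rest, effort = self._pair(rng.uniform(0, 0.2, size=100), rng.uniform(0.5, 1.5, size=100))
        r = np.percentile(rest.values[:, 0], 95)
        e = np.percentile(effort.values[:, 0], 95)
        prev = r
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            v = calibrate(rest, effort, fraction=frac).calibrated_value
            assert r < v < e
            assert v > prev
            prev = v

    def test_identical_recordings_raise_calibration_error(self):
        rest, effort = self._pair(np.ones(20), np.ones(20))
        with pytest.raises(CalibrationError, match="separable") as exc:
            calibrate(rest, effort)
        assert exc.value.rest_stat == exc.value.effort_stat

    def test_wrong_roles_rejected(self):
        rest = make_session(np.zeros(10), role="baseline")
        effort = make_session(np.ones(10), role="effort_calibration")
        with pytest.raises(ValidationError, match="rest_calibration"):
            calibrate(rest, effort)
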