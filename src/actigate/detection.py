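"""Threshold calibration, activation mapping, and event extraction.

The whole engine hinges on one comparison: an output is active exactly while
the scalar sensor value *strictly exceeds* a threshold.  Everything in this
module exists to supply that threshold (calibration, optional adaptation) and
to turn the per-sample comparison into clean, timestamped activation events
(optional hysteresis/debounce).

The threshold can be static — fixed by a short calibration procedure against
a rest recording and a best-effort recording — or adaptive, in which case it
relaxes each sample toward a weighted average of the maximum and the mean of
the activity over the trailing five-second window, so it gradually tracks the
user's current level of activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError, ValidationError
from .sensor_io import SensorSession, magnitude_series

__all__ = [
    "ThresholdPolicy",
    "DebounceConfig",
    "ActivationEvent",
    "input2output",
    "adaptive_target",
    "effective_threshold_series",
    "detect_events",
    "calibrate",
]


@dataclass
class ThresholdPolicy:
    """Calibrated activation threshold plus optional adaptive-update settings.

    Parameters
    ----------
    calibrated_value : float
        The static threshold, in signal units; also the starting point (and
        empty-window fallback) of the adaptive threshold.  Must be > 0.
    adaptive_enabled : bool
        If set, the effective threshold relaxes toward the windowed target.
    window_seconds : float
        Length of the trailing activity window.  Default 5 s.
    max_weight : float
        Weight on the windowed maximum; ``1 - max_weight`` goes on the
        windowed mean.  In [0, 1], default 0.5.
    smoothing_alpha : float
        Per-sample relaxation step toward the windowed target, in (0, 1].
        1.0 jumps straight to the target; small values adapt gradually.
    floor : float or None
        Optional lower bound for the adaptive threshold.  Default ``None``:
        the threshold relaxes freely, which lets activation cease entirely on
        a signal that settles to a constant.
    """

    calibrated_value: float
    adaptive_enabled: bool = False
    window_seconds: float = 5.0
    max_weight: float = 0.5
    smoothing_alpha: float = 0.1
    floor: float | None = None

    def __post_init__(self) -> None:
        if not self.calibrated_value > 0:
            raise ValidationError("calibrated_value must be > 0")
        if not self.window_seconds > 0:
            raise ValidationError("window_seconds must be > 0")
        if not 0.0 <= self.max_weight <= 1.0:
            raise ValidationError("max_weight must be in [0, 1]")
        if not 0.0 < self.smoothing_alpha <= 1.0:
            raise ValidationError("smoothing_alpha must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "calibrated_value": self.calibrated_value,
            "adaptive_enabled": self.adaptive_enabled,
            "window_seconds": self.window_seconds,
            "max_weight": self.max_weight,
            "smoothing_alpha": self.smoothing_alpha,
            "floor": self.floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdPolicy":
        return cls(**d)


@dataclass
class DebounceConfig:
    """Chatter suppression around the raw comparison.

    All-zero (the default) reproduces the raw per-sample comparison exactly.

    ``hysteresis_fraction`` lowers the release threshold to
    ``threshold * (1 - hysteresis_fraction)`` once active, so a signal
    hovering at the threshold does not toggle every sample.  Gaps shorter
    than ``min_inactive_seconds`` are merged into one event, then events
    shorter than ``min_active_seconds`` are dropped.
    """

    hysteresis_fraction: float = 0.0
    min_active_seconds: float = 0.0
    min_inactive_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.hysteresis_fraction < 0 or self.hysteresis_fraction >= 1:
            raise ValidationError("hysteresis_fraction must be in [0, 1)")
        if self.min_active_seconds < 0 or self.min_inactive_seconds < 0:
            raise ValidationError("debounce durations must be >= 0")


@dataclass
class ActivationEvent:
    """A contiguous interval during which the signal exceeded the threshold.

    ``offset_t`` is the time of the first sample at which the event is over
    (for an event running to the end of the recording: the last timestamp
    plus one trailing inter-sample interval), so ``offset_t > onset_t`` even
    for a single-sample event.
    """

    onset_t: float
    offset_t: float
    peak_value: float
    threshold_at_onset: float

    def __post_init__(self) -> None:
        if not self.offset_t > self.onset_t:
            raise ValidationError("offset_t must exceed onset_t")
        if not self.peak_value > self.threshold_at_onset:
            raise ValidationError("peak_value must exceed threshold_at_onset")

    @property
    def duration_s(self) -> float:
        return self.offset_t - self.onset_t


def input2output(sensorvalue: float, threshold: float) -> bool:
    """The core activation mapping: active iff value strictly exceeds threshold.

    Strict inequality means a value exactly at the threshold deactivates.
    """
    return sensorvalue > threshold


def adaptive_target(window_values: Sequence[float] | np.ndarray, policy: ThresholdPolicy) -> float:
    """Weighted average of the windowed maximum and mean activity.

    Returns ``max_weight * max(window) + (1 - max_weight) * mean(window)``;
    an empty window falls back to the calibrated value.  For any weight in
    [0, 1] the result is sandwiched between the window min and max.
    """
    w = np.asarray(window_values, dtype=float)
    if w.size == 0:
        return policy.calibrated_value
    return float(policy.max_weight * w.max() + (1.0 - policy.max_weight) * w.mean())


def _validate_series(values, times) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape or values.ndim != 1:
        raise ValidationError("values and times must be 1-D and the same length")
    if values.size == 0:
        raise ValidationError("empty signal")
    if values.size > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    return values, times


def effective_threshold_series(
    values: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
    policy: ThresholdPolicy,
) -> np.ndarray:
    """Per-sample effective threshold.

    Static policy: a constant series at the calibrated value.  Adaptive
    policy: ``thr[0] = calibrated_value`` and

        thr[i] = (1 - alpha) * thr[i-1] + alpha * target_i

    where ``target_i`` is :func:`adaptive_target` over the values whose times
    fall in the trailing half-open window ``(t_i - window_seconds, t_i]``.
    Gradual adaptation is thus realised as exponential relaxation: on a
    constant input ``c`` the gap ``|thr[i] - c|`` shrinks by a factor
    ``(1 - alpha)`` per sample (closed form ``(1-alpha)**i * |thr[0] - c|``).
    """
    values, times = _validate_series(values, times)
    n = values.size
    if not policy.adaptive_enabled:
        return np.full(n, policy.calibrated_value, dtype=float)
    thr = np.empty(n, dtype=float)
    thr[0] = policy.calibrated_value
    alpha = policy.smoothing_alpha
    for i in range(1, n):
        lo = int(np.searchsorted(times, times[i] - policy.window_seconds, side="right"))
        target = adaptive_target(values[lo : i + 1], policy)
        t_new = (1.0 - alpha) * thr[i - 1] + alpha * target
        # The relaxation can stall short of its fixed point: per step the gap
        # contracts by alpha but picks up ~eps of rounding error, so it
        # plateaus around eps/alpha. Snap at that level so a constant signal
        # really does stop activating (strict comparison).
        if abs(t_new - target) <= 8.0 * np.finfo(float).eps / alpha * max(1.0, abs(target)):
            t_new = target
        if policy.floor is not None:
            t_new = max(t_new, policy.floor)
        thr[i] = t_new
    return thr


def _tail_interval(times: np.ndarray, sample_rate_hz: float | None) -> float:
    if times.size > 1:
        return float(np.median(np.diff(times)))
    return 1.0 / sample_rate_hz if sample_rate_hz else 1.0


def detect_events(
    values: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
    policy: ThresholdPolicy,
    debounce: DebounceConfig | None = None,
    sample_rate_hz: float | None = None,
) -> list[ActivationEvent]:
    """Extract activation events from a scalar signal.

    With all-zero debounce the events are exactly the maximal runs of samples
    where :func:`input2output` holds against the effective threshold.  With
    hysteresis an active run ends only when the value drops to or below
    ``threshold * (1 - hysteresis_fraction)``.  Short gaps are merged first,
    then short events dropped (see :class:`DebounceConfig`).  Events come out
    time-ordered and non-overlapping.
    """
    values, times = _validate_series(values, times)
    debounce = debounce or DebounceConfig()
    thr = effective_threshold_series(values, times, policy)
    tail = _tail_interval(times, sample_rate_hz)
    n = values.size

    # Raw runs from the two-threshold (activate/release) state machine.
    runs: list[tuple[int, int]] = []  # [start, end) sample indices
    active = False
    start = 0
    for i in range(n):
        if not active:
            if values[i] > thr[i]:
                active = True
                start = i
        else:
            if values[i] <= thr[i] * (1.0 - debounce.hysteresis_fraction):
                runs.append((start, i))
                active = False
    if active:
        runs.append((start, n))

    def bounds(run: tuple[int, int]) -> tuple[float, float]:
        s, e = run
        onset = float(times[s])
        offset = float(times[e]) if e < n else float(times[-1] + tail)
        return onset, offset

    # Merge gaps shorter than min_inactive_seconds, then drop short runs.
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged:
            prev = merged[-1]
            gap = bounds(run)[0] - bounds(prev)[1]
            if gap < debounce.min_inactive_seconds:
                merged[-1] = (prev[0], run[1])
                continue
        merged.append(run)

    events: list[ActivationEvent] = []
    for s, e in merged:
        onset, offset = bounds((s, e))
        if offset - onset < debounce.min_active_seconds:
            continue
        events.append(
            ActivationEvent(
                onset_t=onset,
                offset_t=offset,
                peak_value=float(values[s:e].max()),
                threshold_at_onset=float(thr[s]),
            )
        )
    return events


def activation_series(
    values: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
    policy: ThresholdPolicy,
    debounce: DebounceConfig | None = None,
    sample_rate_hz: float | None = None,
) -> np.ndarray:
    """Boolean per-sample activation derived from the detected events.

    A sample is active iff its time falls inside some event's
    ``[onset_t, offset_t)`` interval.  This is the series the output engine
    consumes.
    """
    values, times = _validate_series(values, times)
    events = detect_events(values, times, policy, debounce, sample_rate_hz)
    out = np.zeros(times.size, dtype=bool)
    for ev in events:
        out |= (times >= ev.onset_t) & (times < ev.offset_t)
    return out


def calibrate(
    rest: SensorSession,
    effort: SensorSession,
    fraction: float = 0.5,
    percentile: float = 95.0,
    remove_gravity: bool = True,
    axis_mask: tuple[bool, ...] | None = None,
    **policy_kwargs,
) -> ThresholdPolicy:
    """Fix the activation threshold from a rest and a best-effort recording.

    The user first holds still (rest recording), then moves as much as they
    can (effort recording).  With ``r`` and ``e`` the given percentile of the
    two magnitude series, the threshold is placed a ``fraction`` of the way
    up the separation band:  ``r + fraction * (e - r)``.  The percentile
    (default 95th) rather than the maximum keeps a single spiked sample from
    dominating the calibration.

    Raises
    ------
    CalibrationError
        If ``e <= r`` — the effort recording shows no separable movement
        signal above rest.
    """
    if rest.role != "rest_calibration":
        raise ValidationError(f"rest session has role {rest.role!r}, expected 'rest_calibration'")
    if effort.role != "effort_calibration":
        raise ValidationError(f"effort session has role {effort.role!r}, expected 'effort_calibration'")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    if not 0.0 < percentile <= 100.0:
        raise ValidationError("percentile must be in (0, 100]")
    r = float(np.percentile(magnitude_series(rest, remove_gravity, axis_mask), percentile))
    e = float(np.percentile(magnitude_series(effort, remove_gravity, axis_mask), percentile))
    if e <= r:
        raise CalibrationError(
            f"no separable movement signal: effort statistic {e:.6g} <= rest statistic {r:.6g}",
            rest_stat=r,
            effort_stat=e,
        )
    return ThresholdPolicy(calibrated_value=r + fraction * (e - r), **policy_kwargs)
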