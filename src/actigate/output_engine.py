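"""The five output categories as deterministic, headless state machines.

The engine never touches an audio device: its contract is a timestamped
*action log* (what was triggered/played/paused and when) plus a per-track
*gain trace* (the volume automation curve).  An optional playback adapter can
render these, but correctness lives entirely in the logs, which makes every
mode testable byte-for-byte.

Categories
----------
Sound
    Fires a short sound effect on every activation instance (rising edge);
    holding the activation does not re-fire.
Music
    A longer sample: activation starts/continues playback, inactivity pauses
    it.  Playback position persists across pauses (resume, not restart;
    restart is available via ``resume=False``).
Volume
    Ramps the device volume up while active and down while inactive, linearly
    at ``ramp_rate`` gain units per second, clamped to [0, 1].
PausePlay
    Emits a media play/pause toggle on each rising edge, like the button on a
    multimedia headset.
MultiTrack
    Per-track Volume behaviour: each activation channel gates the gain of one
    stem of a song playing in synchrony (stems are pre-separated upstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CATEGORIES",
    "OutputMode",
    "OutputAction",
    "GainTrace",
    "run_output",
    "write_action_log",
    "read_action_log",
]

CATEGORIES = ("Sound", "Music", "Volume", "PausePlay", "MultiTrack")

_ACTION_KINDS = ("trigger_sound", "play", "pause", "media_toggle", "set_gain")


@dataclass
class OutputMode:
    """Configuration of one output category.

    ``assets`` are media file references: at least one sound/sample for
    Sound/Music, one file per track for MultiTrack (ignored for Volume and
    PausePlay, which act on the device/an external app).
    """

    category: str
    assets: tuple[str, ...] = ()
    ramp_rate: float = 0.2
    retrigger_edge_only: bool = True
    initial_gain: float = 0.0
    resume: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown output category {self.category!r}")
        self.assets = tuple(self.assets)
        if self.category in ("Sound", "Music", "MultiTrack") and len(self.assets) < 1:
            raise ValidationError(f"{self.category} mode requires at least one asset")
        if self.category in ("Volume", "MultiTrack") and not self.ramp_rate > 0:
            raise ValidationError("ramp_rate must be > 0")
        if not 0.0 <= self.initial_gain <= 1.0:
            raise ValidationError("initial_gain must be in [0, 1]")

    @property
    def n_tracks(self) -> int:
        return len(self.assets) if self.category == "MultiTrack" else 1


@dataclass
class OutputAction:
    """One timestamped thing the output did."""

    t: float
    kind: str
    track_index: int | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError("action time must be non-negative")
        if self.kind not in _ACTION_KINDS:
            raise ValidationError(f"unknown action kind {self.kind!r}")
        if self.value is not None and not 0.0 <= self.value <= 1.0:
            raise ValidationError("gain value must be in [0, 1]")


@dataclass
class GainTrace:
    """Per-track gain time series, clamped to [0, 1], linear between samples."""

    times: np.ndarray
    gains: np.ndarray  # shape (n, n_tracks); n_tracks may be 0 for trigger modes

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.ndim == 1:
            self.gains = self.gains[:, None]
        if self.gains.shape[0] != self.times.shape[0]:
            raise ValidationError("gain trace must have one row per time sample")
        if self.gains.size and (self.gains.min() < 0 or self.gains.max() > 1):
            raise ValidationError("gains must lie in [0, 1]")

    @property
    def n_tracks(self) -> int:
        return int(self.gains.shape[1])


def _as_activation(activation, n_tracks: int) -> np.ndarray:
    a = np.asarray(activation, dtype=bool)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[1] != n_tracks:
        raise ValidationError(f"expected {n_tracks} activation channel(s), got {a.shape[1]}")
    return a


def _edges(chan: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of rising and falling edges; index 0 counts as rising if active."""
    prev = np.concatenate(([False], chan[:-1]))
    rising = np.flatnonzero(chan & ~prev)
    falling = np.flatnonzero(~chan & prev)
    return rising, falling


def _ramp_gains(chan: np.ndarray, times: np.ndarray, rate: float, g0: float) -> np.ndarray:
    g = np.empty(times.size, dtype=float)
    g[0] = g0
    for i in range(1, times.size):
        dt = times[i] - times[i - 1]
        step = rate * dt if chan[i - 1] else -rate * dt
        g[i] = min(1.0, max(0.0, g[i - 1] + step))
    return g


def run_output(
    activation,
    times,
    mode: OutputMode,
) -> tuple[list[OutputAction], GainTrace]:
    """Drive one output mode with an activation series.

    Parameters
    ----------
    activation : bool array, shape (n,) or (n, n_tracks)
        Per-sample activation; MultiTrack takes one channel per track.
    times : float array, shape (n,)
        Sample times, strictly increasing.
    mode : OutputMode

    Returns
    -------
    actions, trace
        The timestamped action log and the gain trace.  An empty activation
        series yields an empty log and a flat single-point trace at the
        initial gain (for gain-carrying modes).
    """
    times = np.asarray(times, dtype=float)
    a = np.asarray(activation, dtype=bool)
    n = times.size
    if a.shape[:1] != (n,) and not (n == 0 and a.size == 0):
        raise ValidationError("activation and times must agree in length")
    if n == 0:
        if mode.category in ("Volume", "MultiTrack"):
            k = mode.n_tracks
            return [], GainTrace(times=np.array([0.0]), gains=np.full((1, k), mode.initial_gain))
        return [], GainTrace(times=np.array([0.0]), gains=np.empty((1, 0)))
    if n > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")

    actions: list[OutputAction] = []

    if mode.category == "Sound":
        chan = _as_activation(a, 1)[:, 0]
        rising, _ = _edges(chan)
        for i in rising:
            actions.append(OutputAction(t=float(times[i]), kind="trigger_sound"))
        trace = GainTrace(times=times, gains=np.empty((n, 0)))

    elif mode.category == "PausePlay":
        chan = _as_activation(a, 1)[:, 0]
        rising, _ = _edges(chan)
        for i in rising:
            actions.append(OutputAction(t=float(times[i]), kind="media_toggle"))
        trace = GainTrace(times=times, gains=np.empty((n, 0)))

    elif mode.category == "Music":
        chan = _as_activation(a, 1)[:, 0]
        rising, falling = _edges(chan)
        for i in sorted(np.concatenate((rising, falling))):
            kind = "play" if chan[i] else "pause"
            actions.append(OutputAction(t=float(times[i]), kind=kind))
        trace = GainTrace(times=times, gains=np.empty((n, 0)))

    elif mode.category in ("Volume", "MultiTrack"):
        k = mode.n_tracks
        chans = _as_activation(a, k)
        gains = np.empty((n, k), dtype=float)
        for j in range(k):
            gains[:, j] = _ramp_gains(chans[:, j], times, mode.ramp_rate, mode.initial_gain)
            rising, falling = _edges(chans[:, j])
            for i in sorted(np.concatenate((rising, falling))):
                actions.append(
                    OutputAction(
                        t=float(times[i]),
                        kind="set_gain",
                        track_index=j if mode.category == "MultiTrack" else None,
                        value=float(gains[i, j]),
                    )
                )
        actions.sort(key=lambda x: (x.t, x.track_index if x.track_index is not None else -1))
        trace = GainTrace(times=times, gains=gains)

    else:  # pragma: no cover - guarded by OutputMode validation
        raise ValidationError(f"unknown category {mode.category!r}")

    return actions, trace


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".gains.csv")


def write_action_log(actions: list[OutputAction], trace: GainTrace, path: str | Path) -> None:
    """Write the action log as JSONL plus a sidecar gain-trace CSV.

    One JSON object per action (keys sorted, floats via ``repr``), so the
    same inputs always produce byte-identical files and the round trip via
    :func:`read_action_log` is lossless.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for act in actions:
            fh.write(
                json.dumps(
                    {"t": act.t, "kind": act.kind, "track_index": act.track_index, "value": act.value},
                    sort_keys=True,
                )
                + "\n"
            )
    cols = {"t": trace.times}
    for j in range(trace.n_tracks):
        cols[f"track_{j}"] = trace.gains[:, j]
    pd.DataFrame(cols).to_csv(_sidecar(path), index=False, lineterminator="\n")


def read_action_log(path: str | Path) -> tuple[list[OutputAction], GainTrace]:
    """Read back an action log and its sidecar gain trace."""
    path = Path(path)
    actions = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            actions.append(
                OutputAction(t=d["t"], kind=d["kind"], track_index=d["track_index"], value=d["value"])
            )
    frame = pd.read_csv(_sidecar(path), float_precision="round_trip")
    gains = frame[[c for c in frame.columns if c.startswith("track_")]].to_numpy()
    if gains.shape[1] == 0:
        gains = np.empty((frame.shape[0], 0))
    return actions, GainTrace(times=frame["t"].to_numpy(), gains=gains)
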