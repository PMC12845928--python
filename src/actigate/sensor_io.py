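"""Session data model, on-disk recording format, and the sensor registry.

A *session* is a timestamped multi-channel recording from a single wearable
sensor placement (e.g. an accelerometer strapped to the left wrist).  Sessions
are the universal input to the detection and analytics layers; everything
downstream consumes the scalar *magnitude series* derived from them.

On-disk format
--------------
Plain CSV, UTF-8, ``.`` decimal separator, LF line endings:

* a ``#``-prefixed ``key: value`` header block declaring ``sensor_kind``,
  ``signal``, ``units``, ``sample_rate_hz``, ``placement`` and ``role``;
* one column-header row ``t,c1,c2,...``;
* data rows: session-relative time in seconds followed by channel values.

Numeric values are serialised with ``repr`` so a write/read round trip is
exact to well below 1e-9 per value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "SIGNAL_CHANNELS",
    "SESSION_ROLES",
    "SensorKind",
    "SensorSession",
    "load_registry",
    "read_session",
    "write_session",
    "magnitude_series",
]

#: Channel count per signal label: inertial/magnetic signals are triaxial,
#: the rest are single-channel.
SIGNAL_CHANNELS = {
    "Acc": 3,
    "Gyr": 3,
    "Mag": 3,
    "Force": 1,
    "EMG": 1,
    "Bar": 1,
    "Light": 1,
}

SESSION_ROLES = ("baseline", "intervention", "rest_calibration", "effort_calibration")

_HEADER_FIELDS = ("sensor_kind", "signal", "units", "sample_rate_hz", "placement", "role")


@dataclass(frozen=True)
class SensorKind:
    """A supported sensor device and the signals it can stream."""

    name: str
    signals: frozenset[str]

    def __post_init__(self) -> None:
        unknown = set(self.signals) - set(SIGNAL_CHANNELS)
        if unknown:
            raise ValidationError(f"unknown signal labels {sorted(unknown)} for sensor {self.name!r}")

    def channel_count(self, signal: str) -> int:
        if signal not in self.signals:
            raise ValidationError(f"sensor {self.name!r} does not provide signal {signal!r}")
        return SIGNAL_CHANNELS[signal]


def load_registry(extra_path: str | Path | None = None) -> dict[str, SensorKind]:
    """Load the shipped sensor registry, optionally merged with a user file.

    The registry is a JSON mapping of device name to its signal list; the
    shipped file enumerates the commercial devices the original app supports
    (smart-device built-in IMU, Movesense, Metamotion, Cosmo Switch, Retisense
    Insight, Gaitup Physilog, M40 Muscle Sense, Puck.js).
    """
    raw = json.loads(resources.files("actigate.data").joinpath("sensors.json").read_text())
    if extra_path is not None:
        raw.update(json.loads(Path(extra_path).read_text()))
    return {name: SensorKind(name=name, signals=frozenset(sigs)) for name, sigs in raw.items()}


@dataclass
class SensorSession:
    """A validated single-sensor recording.

    Attributes
    ----------
    sensor_kind : str
        Registry name of the device (free text for user-defined devices).
    signal : str
        One of the labels in :data:`SIGNAL_CHANNELS`.
    units : str
        Unit label of the channel values (metadata only; thresholds are
        calibrated in the same units, so no conversion layer exists).
    sample_rate_hz : float
        Nominal sampling rate; informative, no operation depends on it being
        exact.
    placement : str
        Free-text body location, e.g. ``"left wrist"``.
    role : str
        One of :data:`SESSION_ROLES`.
    times : ndarray, shape (n,)
        Session-relative timestamps in seconds, strictly increasing, first
        value >= 0.
    values : ndarray, shape (n, k)
        Channel readings; ``k`` must match the signal's channel count.
    """

    sensor_kind: str
    signal: str
    units: str
    sample_rate_hz: float
    placement: str
    role: str
    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0] and self.values.shape[1] == self.times.shape[0]:
            self.values = self.values.T
        self.validate()

    def validate(self) -> None:
        if self.signal not in SIGNAL_CHANNELS:
            raise ValidationError(f"unknown signal {self.signal!r}")
        if self.role not in SESSION_ROLES:
            raise ValidationError(f"unknown session role {self.role!r}; expected one of {SESSION_ROLES}")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        n = self.times.shape[0]
        if n == 0:
            raise ValidationError("session has no samples")
        if self.values.ndim != 2 or self.values.shape[0] != n:
            raise ValidationError("values must have one row per sample")
        expected = SIGNAL_CHANNELS[self.signal]
        if self.values.shape[1] != expected:
            raise ValidationError(
                f"signal {self.signal!r} expects {expected} channel(s), got {self.values.shape[1]}"
            )
        if self.times[0] < 0:
            raise ValidationError("first timestamp must be >= 0")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 2
            raise ValidationError(f"timestamps must be strictly increasing; violation at row {row}")
        if n > 1:
            nominal = 1.0 / self.sample_rate_hz
            med = float(np.median(dt))
            if not (0.8 * nominal <= med <= 1.2 * nominal):
                warnings.warn(
                    f"median inter-sample interval {med:.6g}s deviates >20% from nominal "
                    f"{nominal:.6g}s (rate {self.sample_rate_hz} Hz)",
                    stacklevel=2,
                )

    @property
    def n_samples(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.values.shape[1])

    @property
    def duration_s(self) -> float:
        """Elapsed time covered by the samples plus one trailing interval."""
        if self.n_samples == 1:
            return 1.0 / self.sample_rate_hz
        dt = np.diff(self.times)
        return float(self.times[-1] - self.times[0] + np.median(dt))

    def with_role(self, role: str) -> "SensorSession":
        return replace(self, role=role)


def read_session(path: str | Path) -> SensorSession:
    """Read a session file, validating header and data layout.

    Raises
    ------
    FormatError
        If the header block is missing a required field.
    ValidationError
        On non-monotonic timestamps (reporting the first offending data row)
        or a wrong column count.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
    missing = [f for f in _HEADER_FIELDS if f not in header]
    if missing:
        raise FormatError(f"{path}: header missing required field(s): {', '.join(missing)}")
    try:
        rate = float(header["sample_rate_hz"])
    except ValueError as exc:
        raise FormatError(f"{path}: sample_rate_hz is not numeric: {header['sample_rate_hz']!r}") from exc

    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if frame.shape[0] == 0:
        raise ValidationError(f"{path}: session has no data rows")
    if frame.columns[0] != "t":
        raise FormatError(f"{path}: first data column must be 't', got {frame.columns[0]!r}")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax()) + 1
        raise ValidationError(f"{path}: wrong column count or missing value at data row {row}")
    return SensorSession(
        sensor_kind=header["sensor_kind"],
        signal=header["signal"],
        units=header["units"],
        sample_rate_hz=rate,
        placement=header["placement"],
        role=header["role"],
        times=frame["t"].to_numpy(),
        values=frame.iloc[:, 1:].to_numpy(),
    )


def write_session(session: SensorSession, path: str | Path) -> None:
    """Write a session file readable by :func:`read_session`.

    Values are serialised with ``repr`` (shortest exact decimal), so the
    round trip reproduces every float bit-exactly.
    """
    session.validate()
    path = Path(path)
    cols = ",".join(f"c{i + 1}" for i in range(session.n_channels))
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sensor_kind: {session.sensor_kind}\n")
        fh.write(f"# signal: {session.signal}\n")
        fh.write(f"# units: {session.units}\n")
        fh.write(f"# sample_rate_hz: {session.sample_rate_hz!r}\n")
        fh.write(f"# placement: {session.placement}\n")
        fh.write(f"# role: {session.role}\n")
        fh.write(f"t,{cols}\n")
        for t, row in zip(session.times, session.values):
            fh.write(repr(float(t)) + "," + ",".join(repr(float(v)) for v in row) + "\n")


def magnitude_series(
    session: SensorSession,
    remove_gravity: bool = False,
    axis_mask: tuple[bool, ...] | None = None,
) -> np.ndarray:
    """Reduce a multi-channel session to the scalar series the detector gates on.

    Per sample, the Euclidean norm of the channel vector.  With
    ``remove_gravity`` and an accelerometer signal, the session-wide per-axis
    median is subtracted first — a constant orientation offset vanishes while
    intermittent movement bursts survive (the median is robust to them).
    ``axis_mask`` restricts the norm to a subset of channels, for recordings
    where only some axes are meaningful.
    """
    values = session.values
    if axis_mask is not None:
        mask = np.asarray(axis_mask, dtype=bool)
        if mask.shape[0] != values.shape[1]:
            raise ValidationError(
                f"axis_mask length {mask.shape[0]} != channel count {values.shape[1]}"
            )
        if not mask.any():
            raise ValidationError("axis_mask must keep at least one channel")
        values = values[:, mask]
    if remove_gravity and session.signal == "Acc":
        values = values - np.median(values, axis=0, keepdims=True)
    return np.linalg.norm(values, axis=1)
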