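"""Synthetic sensor sessions with controlled movement structure.

The generator emulates what a wrist/ankle accelerometer sees during a
feedback session with a person who moves intermittently and voluntarily:
a constant gravity component, a Gaussian noise floor, and short voluntary
movement *bursts* — damped sinusoids on random 3-D directions — whose onsets
follow a homogeneous Poisson process.  The burst rate is the single quantity
an intervention manipulates: a paired cohort draws a per-subject
multiplicative effect on the feedback-session rate from a log-normal
distribution, so non-responders (effect < 1) arise naturally.

Everything is deterministic given the master seed; per-subject, per-role
seeds are derived by numpy ``SeedSequence`` spawn keys, stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .sensor_io import SensorSession, write_session

__all__ = ["MovementModel", "CohortSpec", "generate_session", "generate_cohort"]

_ROLE_CODES = {"baseline": 0, "intervention": 1, "rest_calibration": 2, "effort_calibration": 3}


@dataclass
class MovementModel:
    """Generative model of one recording condition.

    Parameters
    ----------
    burst_rate_hz : float
        Expected voluntary-movement bursts per second (Poisson).  Default
        0.2/s — one burst every five seconds on average, a plausible rate of
        self-initiated movement for the target population.
    burst_amplitude : float
        Peak magnitude of a burst, in signal units (g for an accelerometer).
    burst_duration_s : float
        Length of each burst envelope.
    burst_freq_hz, burst_decay : float
        The burst waveform is ``amplitude * exp(-decay*tau) * sin(2*pi*f*tau)``
        on a random unit direction; ~4 Hz with a 4/s decay resembles a single
        voluntary limb oscillation.
    noise_sd : float
        Per-axis Gaussian sensor noise, signal units.
    gravity : tuple of 3 floats
        Constant vector added to every sample (accelerometer at rest reads
        1 g along the vertical).
    seed : int
        Seed for this session's random stream.
    """

    burst_rate_hz: float = 0.2
    burst_amplitude: float = 1.0
    burst_duration_s: float = 0.8
    burst_freq_hz: float = 4.0
    burst_decay: float = 4.0
    noise_sd: float = 0.02
    gravity: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_rate_hz < 0:
            raise ValidationError("burst_rate_hz must be >= 0")
        if self.burst_amplitude < 0 or self.burst_duration_s < 0 or self.noise_sd < 0:
            raise ValidationError("amplitude, duration and noise_sd must be >= 0")


@dataclass
class CohortSpec:
    """A paired baseline/intervention cohort with a known activity effect.

    Per subject, the intervention-session burst rate is the baseline rate
    times ``effect_multiplier * LogNormal(0, effect_sigma)``.  A multiplier
    of 1 with sigma 0 is the exact null (identical conditions); sigma > 0
    spreads subjects, letting some land below 1 (non-responders).
    """

    n_subjects: int = 18
    baseline_model: MovementModel = None  # type: ignore[assignment]
    effect_multiplier: float = 2.0
    effect_sigma: float = 0.25
    session_duration_s: float = 300.0
    sample_rate_hz: float = 50.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_model is None:
            self.baseline_model = MovementModel()
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.session_duration_s <= 0:
            raise ValidationError("session_duration_s must be > 0")
        if self.effect_multiplier <= 0 or self.effect_sigma < 0:
            raise ValidationError("effect_multiplier must be > 0 and effect_sigma >= 0")


def _subject_seed(master_seed: int, subject: int, role: str) -> int:
    """Stable per-subject, per-role seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(subject, _ROLE_CODES[role]))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_session(
    model: MovementModel,
    duration_s: float = 300.0,
    sample_rate_hz: float = 50.0,
    role: str = "baseline",
    placement: str = "left wrist",
) -> SensorSession:
    """Simulate one accelerometer session from a movement model.

    Samples are ``gravity + sum of bursts + per-axis Gaussian noise``;
    overlapping bursts superpose additively.  Deterministic given
    ``model.seed``.
    """
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise ValidationError("duration_s and sample_rate_hz must be > 0")
    rng = np.random.default_rng(model.seed)
    n = max(1, int(round(duration_s * sample_rate_hz)))
    times = np.arange(n) / sample_rate_hz
    values = np.tile(np.asarray(model.gravity, dtype=float), (n, 1))

    n_bursts = rng.poisson(model.burst_rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n_bursts))
    for onset in onsets:
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        if norm == 0:  # pragma: no cover - probability zero
            direction = np.array([1.0, 0.0, 0.0])
        else:
            direction = direction / norm
        lo = int(np.searchsorted(times, onset, side="left"))
        hi = int(np.searchsorted(times, onset + model.burst_duration_s, side="right"))
        tau = times[lo:hi] - onset
        wave = model.burst_amplitude * np.exp(-model.burst_decay * tau) * np.sin(
            2.0 * np.pi * model.burst_freq_hz * tau
        )
        values[lo:hi] += wave[:, None] * direction[None, :]

    if model.noise_sd > 0:
        values += rng.normal(scale=model.noise_sd, size=values.shape)

    return SensorSession(
        sensor_kind="movesense_motion",
        signal="Acc",
        units="g",
        sample_rate_hz=sample_rate_hz,
        placement=placement,
        role=role,
        times=times,
        values=values,
    )


def subject_models(spec: CohortSpec, subject: int) -> tuple[MovementModel, MovementModel]:
    """The baseline and intervention models for one subject (0-based index)."""
    base_seed = _subject_seed(spec.master_seed, subject, "baseline")
    int_seed = _subject_seed(spec.master_seed, subject, "intervention")
    effect_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.master_seed, spawn_key=(subject, 17))
    )
    effect = spec.effect_multiplier * (
        float(effect_rng.lognormal(mean=0.0, sigma=spec.effect_sigma)) if spec.effect_sigma > 0 else 1.0
    )
    baseline = replace(spec.baseline_model, seed=base_seed)
    intervention = replace(
        spec.baseline_model, seed=int_seed, burst_rate_hz=spec.baseline_model.burst_rate_hz * effect
    )
    return baseline, intervention


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write a paired cohort to ``out_dir/subject_XX/{baseline,intervention}.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(spec.n_subjects):
        sub_dir = out_dir / f"subject_{i + 1:02d}"
        sub_dir.mkdir(exist_ok=True)
        base_model, int_model = subject_models(spec, i)
        for role, model in (("baseline", base_model), ("intervention", int_model)):
            session = generate_session(
                model,
                duration_s=spec.session_duration_s,
                sample_rate_hz=spec.sample_rate_hz,
                role=role,
            )
            write_session(session, sub_dir / f"{role}.csv")
    return out_dir
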