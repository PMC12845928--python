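"""Structured run configuration.

One YAML file with sections mirroring the library modules; unknown keys are
rejected so a typo never silently falls back to a default.  CLI flags
override config keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .detection import DebounceConfig, ThresholdPolicy
from .output_engine import OutputMode
from .synthetic import CohortSpec, MovementModel


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SensorConfig(_Section):
    remove_gravity: bool = True
    axis_mask: Optional[list[bool]] = None

    @property
    def mask_tuple(self) -> tuple[bool, ...] | None:
        return tuple(self.axis_mask) if self.axis_mask is not None else None


class ThresholdConfig(_Section):
    adaptive_enabled: bool = False
    window_seconds: float = Field(5.0, gt=0)
    max_weight: float = Field(0.5, ge=0, le=1)
    smoothing_alpha: float = Field(0.1, gt=0, le=1)
    floor: Optional[float] = None
    # calibration knobs
    fraction: float = Field(0.5, gt=0, lt=1)
    percentile: float = Field(95.0, gt=0, le=100)

    def policy(self, calibrated_value: float) -> ThresholdPolicy:
        return ThresholdPolicy(
            calibrated_value=calibrated_value,
            adaptive_enabled=self.adaptive_enabled,
            window_seconds=self.window_seconds,
            max_weight=self.max_weight,
            smoothing_alpha=self.smoothing_alpha,
            floor=self.floor,
        )


class DebounceSection(_Section):
    hysteresis_fraction: float = Field(0.0, ge=0, lt=1)
    min_active_seconds: float = Field(0.0, ge=0)
    min_inactive_seconds: float = Field(0.0, ge=0)

    def build(self) -> DebounceConfig:
        return DebounceConfig(
            hysteresis_fraction=self.hysteresis_fraction,
            min_active_seconds=self.min_active_seconds,
            min_inactive_seconds=self.min_inactive_seconds,
        )


class OutputConfig(_Section):
    category: Literal["Sound", "Music", "Volume", "PausePlay", "MultiTrack"] = "Sound"
    assets: list[str] = ["default.wav"]
    ramp_rate: float = Field(0.2, gt=0)
    initial_gain: float = Field(0.0, ge=0, le=1)
    resume: bool = True

    def build(self) -> OutputMode:
        return OutputMode(
            category=self.category,
            assets=tuple(self.assets),
            ramp_rate=self.ramp_rate,
            initial_gain=self.initial_gain,
            resume=self.resume,
        )


class MetricsConfig(_Section):
    statistic: Literal["mean", "rms", "time_above_threshold"] = "mean"


class SimulateConfig(_Section):
    n_subjects: int = Field(18, ge=1)
    effect_multiplier: float = Field(2.0, gt=0)
    effect_sigma: float = Field(0.25, ge=0)
    session_duration_s: float = Field(300.0, gt=0)
    sample_rate_hz: float = Field(50.0, gt=0)
    master_seed: int = 0
    burst_rate_hz: float = Field(0.2, ge=0)
    burst_amplitude: float = Field(1.0, ge=0)
    noise_sd: float = Field(0.02, ge=0)

    def build(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=self.n_subjects,
            baseline_model=MovementModel(
                burst_rate_hz=self.burst_rate_hz,
                burst_amplitude=self.burst_amplitude,
                noise_sd=self.noise_sd,
            ),
            effect_multiplier=self.effect_multiplier,
            effect_sigma=self.effect_sigma,
            session_duration_s=self.session_duration_s,
            sample_rate_hz=self.sample_rate_hz,
            master_seed=self.master_seed,
        )


class RunConfig(_Section):
    sensor: SensorConfig = SensorConfig()
    threshold: ThresholdConfig = ThresholdConfig()
    debounce: DebounceSection = DebounceSection()
    output: OutputConfig = OutputConfig()
    metrics: MetricsConfig = MetricsConfig()
    simulate: SimulateConfig = SimulateConfig()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RunConfig.model_validate(raw)
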