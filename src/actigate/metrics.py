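"""Session activity quantification and cohort summaries.

A session's *activity* is a scalar summary of its gravity-removed magnitude
series.  Change relative to a baseline session is expressed as the ratio

    ratio_percent = activity / baseline * 100

so 100 means parity; the headline per-subject figure is
``increase_percent = ratio_percent - 100`` (a non-responder comes out
negative).  A cohort is summarised by the median increase, its range, and
the count of subjects with a strictly positive increase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import ThresholdPolicy, activation_series
from .errors import ValidationError
from .sensor_io import SensorSession, magnitude_series, read_session

__all__ = [
    "ACTIVITY_STATISTICS",
    "ActivityReport",
    "CohortSummary",
    "session_activity",
    "activity_ratio",
    "cohort_summary",
    "analyze_cohort",
    "write_reports",
]

ACTIVITY_STATISTICS = ("mean", "rms", "time_above_threshold")


@dataclass
class ActivityReport:
    """Per-subject activity comparison against baseline."""

    session_id: str
    activity: float
    baseline_activity: float
    ratio_percent: float
    increase_percent: float


@dataclass
class CohortSummary:
    n: int
    median_increase: float
    min_increase: float
    max_increase: float
    n_positive: int


def session_activity(
    session: SensorSession,
    statistic: str = "mean",
    policy: ThresholdPolicy | None = None,
    remove_gravity: bool = True,
    axis_mask: tuple[bool, ...] | None = None,
) -> float:
    """Scalar activity summary of one session.

    ``mean`` (default) and ``rms`` summarise the gravity-removed magnitude
    series directly; ``time_above_threshold`` is the fraction of session
    duration spent with activation true, and requires a threshold policy.
    The default statistic is a package choice — no single canonical activity
    measure exists for this kind of recording.
    """
    if statistic not in ACTIVITY_STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; expected one of {ACTIVITY_STATISTICS}")
    mags = magnitude_series(session, remove_gravity=remove_gravity, axis_mask=axis_mask)
    if statistic == "mean":
        return float(mags.mean())
    if statistic == "rms":
        return float(np.sqrt(np.mean(mags**2)))
    if policy is None:
        raise ValidationError("time_above_threshold requires a ThresholdPolicy")
    active = activation_series(mags, session.times, policy, sample_rate_hz=session.sample_rate_hz)
    # Duration-weighted: each sample owns the interval up to the next sample.
    if session.n_samples > 1:
        dt = np.diff(session.times)
        weights = np.concatenate((dt, [np.median(dt)]))
    else:
        weights = np.array([1.0 / session.sample_rate_hz])
    return float(weights[active].sum() / weights.sum())


def activity_ratio(activity: float, baseline: float) -> tuple[float, float]:
    """Baseline-normalised activity, as (ratio_percent, increase_percent).

    ``ratio_percent = activity / baseline * 100`` (100 at parity) and
    ``increase_percent = ratio_percent - 100``.  Scale-invariant: scaling
    both inputs by the same positive constant changes nothing.
    """
    if not baseline > 0:
        raise ValidationError("baseline session shows no activity (baseline must be > 0)")
    if activity < 0:
        raise ValidationError("activity must be non-negative")
    ratio = activity / baseline * 100.0
    return ratio, ratio - 100.0


def cohort_summary(increases) -> CohortSummary:
    """Summarise per-subject increase percentages.

    Median uses the mean-of-two-central-values convention for even n;
    ``n_positive`` counts strictly positive entries (an exact zero is not a
    responder).
    """
    inc = np.asarray(increases, dtype=float)
    if inc.size == 0:
        raise ValidationError("cohort is empty")
    return CohortSummary(
        n=int(inc.size),
        median_increase=float(np.median(inc)),
        min_increase=float(inc.min()),
        max_increase=float(inc.max()),
        n_positive=int((inc > 0).sum()),
    )


def analyze_cohort(
    cohort_dir: str | Path,
    statistic: str = "mean",
    policy: ThresholdPolicy | None = None,
    remove_gravity: bool = True,
    axis_mask: tuple[bool, ...] | None = None,
) -> tuple[list[ActivityReport], CohortSummary]:
    """Analyse a directory of paired sessions.

    Layout: ``cohort_dir/<subject>/{baseline,intervention}.csv``.  Each
    subject contributes one :class:`ActivityReport`; missing roles raise a
    validation error naming the subject.
    """
    cohort_dir = Path(cohort_dir)
    subjects = sorted(p for p in cohort_dir.iterdir() if p.is_dir())
    if not subjects:
        raise ValidationError(f"no subject directories found under {cohort_dir}")
    reports = []
    for sub in subjects:
        sessions = {}
        for role in ("baseline", "intervention"):
            f = sub / f"{role}.csv"
            if not f.exists():
                raise ValidationError(f"subject {sub.name!r} is missing a {role} session ({f})")
            sessions[role] = read_session(f)
        kwargs = dict(statistic=statistic, policy=policy, remove_gravity=remove_gravity, axis_mask=axis_mask)
        act = session_activity(sessions["intervention"], **kwargs)
        base = session_activity(sessions["baseline"], **kwargs)
        ratio, increase = activity_ratio(act, base)
        reports.append(
            ActivityReport(
                session_id=sub.name,
                activity=act,
                baseline_activity=base,
                ratio_percent=ratio,
                increase_percent=increase,
            )
        )
    summary = cohort_summary([r.increase_percent for r in reports])
    return reports, summary


def write_reports(
    reports: list[ActivityReport],
    summary: CohortSummary,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the per-subject CSV and the cohort JSON; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "activity_report.csv"
    json_path = out_dir / "cohort_summary.json"
    pd.DataFrame([asdict(r) for r in reports]).to_csv(csv_path, index=False, lineterminator="\n")
    json_path.write_text(json.dumps(asdict(summary), indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return csv_path, json_path
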