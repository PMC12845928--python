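# actigate

Threshold-gated movement feedback, headless.

People with severe motor impairments (e.g. cerebral palsy at GMFCS levels
III–V) often cannot operate ordinary instruments, toys or media controls, and
end up spectators rather than participants. A simple and effective assistive
pattern is *contingent feedback*: strap a cheap wearable sensor (IMU, force
pad, EMG) to whatever body part the person can move voluntarily, and have any
movement above a personal threshold immediately trigger a motivating output —
a sound effect, a song, the volume of one instrument stem in a band mix.
`actigate` is a library + CLI implementation of that engine, built to be
testable end to end without hardware or audio: sensors are replayed from
files, outputs are deterministic action logs, and a synthetic-session
generator stands in for participants.

## The model

Everything reduces to one comparison applied per sample to the scalar
magnitude `v(t)` of the sensor signal (Euclidean norm of the channels, with
the per-axis median subtracted first for accelerometers so gravity drops
out):

```
active(t)  ⇔  v(t) > θ(t)
```

The threshold is personal. It is fixed by a short calibration against a rest
recording and a best-effort recording — with `r` and `e` the 95th percentile
of the two magnitude series, `θ = r + fraction·(e − r)` — and can optionally
*adapt* to the user's current activity level: each sample it relaxes with
step `α` toward a weighted average of the maximum and mean activity over the
trailing 5-second window,

```
θ_i = (1 − α)·θ_{i−1} + α·( w·max(W_i) + (1 − w)·mean(W_i) ),
W_i = { v(s) : t_i − 5 s < s ≤ t_i }.
```

Maximal runs of active samples become activation events (optional hysteresis
and debounce suppress chatter), which drive five output modes: **Sound**
(trigger per activation instance), **Music** (play/pause), **Volume**
(linear gain ramp up while active, down while inactive, clamped to [0, 1]),
**PausePlay** (media-key toggle) and **MultiTrack** (per-track Volume, one
sensor channel per instrument stem).

Session-level engagement is quantified against a baseline session by the
ratio statistic

```
ratio% = activity / baseline_activity · 100,     increase% = ratio% − 100,
```

where activity is by default the mean gravity-removed magnitude; a cohort is
summarised by the median increase, its range, and the count of subjects with
a strictly positive increase.

## Worked example

```python
from actigate import (CohortSpec, MovementModel, OutputMode, calibrate,
                      detect_events, magnitude_series, activation_series,
                      run_output, generate_session, generate_cohort,
                      analyze_cohort)

rest = generate_session(MovementModel(burst_rate_hz=0.0, noise_sd=0.02, seed=1),
                        duration_s=10.0, role="rest_calibration")
effort = generate_session(MovementModel(burst_rate_hz=1.5, noise_sd=0.02, seed=2),
                          duration_s=10.0, role="effort_calibration")
policy = calibrate(rest, effort)
print(f"calibrated threshold: {policy.calibrated_value:.3f} g")

session = generate_session(MovementModel(burst_rate_hz=0.4, seed=3),
                           duration_s=60.0, role="intervention")
mags = magnitude_series(session, remove_gravity=True)
events = detect_events(mags, session.times, policy)
active = activation_series(mags, session.times, policy)
actions, _ = run_output(active, session.times,
                        OutputMode(category="Sound", assets=("pop.wav",)))
print(f"{len(events)} activation events, {len(actions)} sound triggers")

spec = CohortSpec(master_seed=42)   # 18 subjects, intervention rate 2x baseline
cohort = generate_cohort(spec, "cohort")
reports, summary = analyze_cohort(cohort)
print(f"median increase: {summary.median_increase:.1f}% "
      f"[{summary.min_increase:.1f}%; {summary.max_increase:.1f}%], "
      f"{summary.n_positive}/{summary.n} positive")
```

prints

```
calibrated threshold: 0.380 g
31 activation events, 31 sound triggers
median increase: 47.7% [0.1%; 89.2%], 18/18 positive
```

The threshold lands between the rest noise floor and the effort percentile;
every detected event produces exactly one sound trigger (one per rising
edge); and on a cohort whose intervention sessions double the baseline
movement-burst rate, the analytics report a clearly positive median activity
increase with all 18 simulated subjects responding.

The same pipeline is available from the shell:

```
actigate simulate --out-dir cohort --seed 42
actigate calibrate rest.csv effort.csv --out policy.json
actigate run cohort/subject_01/intervention.csv policy.json --out-dir run_out
actigate analyze cohort --out-dir analysis
```

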