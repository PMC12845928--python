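# Methods

## Scope and shape

`actigate` is a headless re-implementation of a movement-contingent feedback
engine: recorded sensor sessions in, deterministic activation events, action
logs, gain traces and activity reports out. Live Bluetooth streaming, device
firmware, GUIs and actual audio rendering are deliberately outside the
package: the action log and gain trace *are* the output contract, which makes
every mode reproducible and byte-comparable in tests. Source separation for
MultiTrack stems is likewise upstream — the engine consumes pre-split track
files.

## Signal path

1. **Magnitude reduction.** Multi-channel samples are reduced to a scalar per
   sample by the Euclidean norm. For accelerometer signals the session-wide
   per-axis *median* is subtracted first: a constant orientation/gravity
   offset vanishes exactly, while intermittent movement bursts barely move a
   median. We chose median subtraction over high-pass filtering because it
   introduces no filter parameters and no phase distortion; the cost is that
   a session spent mostly in motion would bias the estimate, which is
   acceptable for the intermittent-movement population this targets. An axis
   mask allows restricting the norm to a channel subset when only some axes
   were meaningfully recorded.

2. **Activation.** A sample is active iff its magnitude *strictly* exceeds
   the effective threshold; equality deactivates. This strictness is kept
   exactly — it is what makes "activation eventually ceases on a constant
   signal" a theorem rather than a race.

3. **Threshold.**
   - *Calibration*: `θ = r + fraction·(e − r)` with `r`, `e` the
     `percentile`-th percentile (default 95) of the rest and effort magnitude
     series. The percentile, not the maximum, so a single spiked sample
     cannot dominate; `e ≤ r` is a hard calibration error (no separable
     movement signal), reported with both statistics. `fraction` defaults to
     0.5 — the midpoint of the separation band.
   - *Adaptation* (optional): per sample,
     `θ_i = (1−α)·θ_{i−1} + α·(w·max W + (1−w)·mean W)` over the trailing
     half-open window `(t_i − 5 s, t_i]`. The window length (5 s) is the
     design's stated memory of "recent activity"; the max/mean weight `w`
     defaults to 0.5 (symmetric, fully configurable) and the step `α`
     defaults to 0.1 per sample. Exponential relaxation was chosen to realise
     "gradual" adaptation with a single parameter and a closed-form
     geometric convergence that the tests verify directly. An empty window
     falls back to the calibrated value. The adaptive threshold relaxes
     freely by default (no floor); a configurable floor exists for
     deployments that must never trigger below the calibrated level. The
     adapted quantity is the same magnitude series being thresholded — the
     simplest reading of "the user's level of activity".

4. **Events.** Maximal runs of active samples become events. An event's
   `offset_t` is the time of the first sample after the run (trailing runs
   extend by the median inter-sample interval), so durations are positive
   even for single-sample events; the oracle tests use the same convention.
   Debounce, all-zero by default so the engine reproduces the raw comparison
   literally: hysteresis lowers the release threshold to
   `θ·(1 − hysteresis_fraction)` while active; gaps shorter than
   `min_inactive_seconds` are merged *first*, then events shorter than
   `min_active_seconds` dropped (merge-then-drop is the usual bout-detection
   order: short dropouts are treated as noise before bout lengths are
   judged).

## Output modes

All five categories are pure functions of (activation series, mode config):
Sound and PausePlay emit one action per rising edge exactly; Music emits
strictly alternating play/pause starting with play, resuming position by
default (restart via config); Volume and MultiTrack integrate a ±`ramp_rate`
slope (zero-order hold of the activation between samples) clamped to [0, 1],
making the gain 1-Lipschitz·ramp_rate by construction. Initial gain defaults
to 0. MultiTrack is per-track Volume with independent channels — changing one
channel provably cannot touch another track's trace. Action logs are JSONL
with sorted keys and `repr`-exact floats; gain traces are CSV sidecars; both
round-trip losslessly and byte-identically.

## File format

Sessions are plain CSV with a `#`-prefixed `key: value` header (sensor kind,
signal, units, nominal rate, placement, role) — inspectable, diffable, and
parseable anywhere. Values are written with `repr`, so write→read reproduces
every float bit-exactly. Units are metadata only: thresholds are calibrated
in the units the session was recorded in, so no conversion layer exists.
Timestamps are session-relative seconds; multi-sensor setups are stored as
one file per sensor in a session directory.

## Activity metric

No canonical definition of "session activity" exists for this kind of
recording, so the statistic is configurable with a documented default: the
mean of the gravity-removed magnitude series (alternatives: RMS, fraction of
time above threshold). The ratio statistic is emitted both ways —
`ratio_percent` (100 at parity) and `increase_percent = ratio_percent − 100`
— because the headline "median increase" figure is naturally read on the
latter scale. Cohort medians use the mean-of-central-pair convention for
even n; responders are counted at strictly positive increase.

## Synthetic sessions

The generator emulates a wrist/ankle accelerometer worn by a person who moves
intermittently: constant gravity vector, per-axis Gaussian noise floor
(default sd 0.02 g), and voluntary-movement bursts — damped sinusoids
(default 4 Hz, decay 4/s, peak 1 g, 0.8 s) on random 3-D directions — with
Poisson onsets (default 0.2/s). Overlapping bursts superpose additively. A
paired cohort multiplies each subject's intervention burst rate by
`effect_multiplier · LogNormal(0, effect_sigma)`; the log-normal spread lets
non-responders (< 1) arise naturally. Default cohort: 18 subjects, 2×
multiplier, sigma 0.25, 300-second sessions at 50 Hz. The session length is
the package's desk-scale stand-in for half-hour clinical sessions: long
enough that Poisson counting noise (~√60 on ~60 baseline bursts) is small
against a 2× rate effect, short enough that full-cohort sweeps run in
seconds. Seeds: subject `i`'s per-role streams come from
`SeedSequence(master_seed, spawn_key=(i, role))`, stable across runs and
platforms.

What the generator does **not** model: biomechanically realistic limb
kinematics, spasticity/tone, sensor drift, orientation changes mid-session,
or heteroscedastic noise. Passing the recovery tests therefore shows the
pipeline correctly measures rate changes under this model's assumptions —
not that the default statistic is optimal for real paediatric recordings.

## Numerical choices

- Adaptive relaxation snaps to its target once the remaining gap falls below
  `8·eps/α`: the float recursion otherwise stalls a few ulps short of its
  fixed point (the gap contracts by α per step but regains ~eps of rounding
  error), which would leave a constant signal active forever under the
  strict comparison.
- Session and log files round-trip exactly because floats are serialised
  with `repr` and parsed with exact (`round_trip`) precision.
- A session whose median inter-sample interval deviates more than 20% from
  the nominal rate warns but is not rejected — the nominal rate is
  informative, and no computation depends on it beyond trailing-interval
  fallbacks.
- Degenerate inputs are hard errors, not NaNs: empty sessions, non-monotonic
  timestamps, zero baselines, inseparable calibration recordings.

## Known limitations

- The adaptive threshold is O(n·window) in the worst case (per-sample window
  max); fine for session-length replays, not tuned for day-long recordings.
- `time_above_threshold` uses duration weights with a median-interval tail
  fallback; on heavily irregular sampling the mean/RMS statistics are the
  safer choice.
- The CLI maps one session to all MultiTrack tracks identically; true
  per-extremity multi-sensor runs should call the library with one
  activation channel per sensor file.
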