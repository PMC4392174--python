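# Methods

`pdmotion` re-creates, at desk scale, the analytics of a smartphone-based
home-monitoring system for Parkinson's disease (PD): three strap-mounted
motor tasks (20 s hand resting tremor, 25-foot walk, 360° turn) are sampled
at 100 Hz by the phone's tri-axial accelerometer (plus gyroscope for
turning), conditioned, summarized into a small feature set, and fed to
detection and severity models validated against expert UPDRS/Hoehn & Yahr
ratings. This note records the models, the parameters that matter, and the
design choices made where the protocol left the design open.

## Signal conditioning

Each recording is collapsed to a scalar series as the per-sample Euclidean
magnitude of the tri-axial samples (translational acceleration for tremor
and walking, angular rate for turning), low-pass filtered with a 4th-order
Butterworth applied forward and backward (zero phase, even-reflection
padding), and mean-subtracted ("zero baseline", which removes the gravity
offset the magnitude carries).

Choices and rationale:

* **Magnitude before baseline.** The magnitude is orientation-robust for a
  strap-mounted phone, and because gravity dominates the vector, a tremor
  oscillation along the gravity axis survives in the magnitude as a signed
  oscillation at its true frequency. Baselining per axis first would
  full-wave-rectify the signal and shift its spectral peak to twice the
  tremor frequency. A per-axis override exists for sensors with a known
  mounting orientation.
* **Cutoffs.** 20 Hz for tremor (tremor content lies below 20 Hz) and
  10 Hz for walking/turning (gait content is concentrated at 2–5 Hz); both
  leave generous margin at fs = 100 Hz. Order 4 keeps passband ripple of
  the squared response below 0.5 % up to half the cutoff.

## Tremor features

The six features are computed from a Welch power spectral density (Hann
window, 50 % overlap, segments of min(10 s, record length), FFT padded to a
grid of at most 0.25 Hz): power integrated over 4–6 Hz (`PF4_6`), its
fraction of the 0–20 Hz power (`%PF4_6`), the 3.5–15 Hz to 0.15–3.5 Hz
power ratio (`PR`), total 0–20 Hz power (`PF0_20`), the maximum density
value (`PEAK_POWER`, (m/s²)²/Hz), and the mean absolute conditioned
acceleration (`AVG_ACC`). Band "power" is the trapezoidal integral of the
one-sided density with interpolated band edges, so `PF4_6 ≤ PF0_20` holds
structurally. The power-ratio denominator is floored at 1e-6 (m/s²)² so
band-free signals report a finite ratio rather than infinity. `AVG_ACC`
averages the full record (an intermittent tremor therefore reports roughly
amplitude × active fraction); an episode-gated variant was considered and
rejected as under-determined without a labelled episode detector.

## Gait and turn features

The walking course is fixed at 25 feet (7.62 m), which removes the need for
drift-prone double integration: stride events are the prominent maxima of
the conditioned series (prominence ≥ max(0.5 m/s², 20 % of the
90th-percentile amplitude), separation ≥ 0.6 s), and

* `CT` = mean inter-stride interval, excluding freeze gaps (inclusive
  variant available),
* `SL` = course length / stride count,
* `SP` = course length / first-to-last-stride time,
* `AVG_ACC` = mean |conditioned| over the ambulation window.

With the phone on one ankle each dominant peak is one full gait cycle of
the instrumented leg, so peaks are strides, not steps. Freezing-of-gait
episodes are inter-stride intervals longer than 1.5 s — below the shortest
published freeze gap (1.7 s) yet above plausible slow strides — reported
with their flanking stride times. Turning uses the angular-rate magnitude
(translational fallback), a 0.3 s minimum step separation, `NUM_TURN` =
step-peak count and `TURN_SP` = 360° / active duration, the active duration
being the first-to-last-step span padded by half the mean step interval on
each side (recording duration when only one step is detected).

## Detection and severity models

Two binary detectors (linear-kernel SVM, C = 1) flag resting tremor
(UPDRS tremor item ≥ 1) from the six tremor features and gait difficulty
(UPDRS gait item ≥ 2) from the six walking/turning features. Three Lasso
regressors estimate Hoehn & Yahr stage and the two UPDRS items from all
twelve features, with the L1 penalty chosen by inner 5-fold CV minimizing
mean squared error. Features are z-scored with training-fold statistics
only. Evaluation is stratified 5-fold cross-validation (by class for
detectors, by label quartile for regressors, falling back to plain shuffled
folds when a stratum is smaller than k); out-of-fold predictions are pooled
and scored once (per-fold values are also reported). Regression predictions
are clipped to the label range (stage [1, 5], items [0, 4]) before the
Pearson correlation. The linear kernel and C = 1 are the lowest-variance
choice for 40 subjects and ≤ 12 features; an RBF kernel is exposed through
configuration. All partitions and fits are deterministic given the run
seed.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated; every generated recording carries exact ground truth.

* **Tremor**: a sinusoid at a frequency drawn uniformly from 4–6 Hz rides
  on the gravity offset of the vertical axis, its peak set to π/2 times the
  target mean absolute acceleration; severity archetypes 0 / 0.47 / 1.7 /
  4.0 / 6.0 m/s² for UPDRS scores 0–4, matching the published mild,
  intermittent-moderate and severe waveforms. Moderate severity gates the
  sinusoid with smoothed bursts at 50 % active fraction. White sensor noise
  (SD 0.1 m/s²) is added on all axes.
* **Walking**: biphasic stride pulses (Gaussian swing lobe, 1.5× larger
  negative stance lobe, matching the published +8/−12 m/s² peaks) on the
  vertical axis. The walk-level cycle time is drawn from N(ct_mean, ct_sd)
  truncated at ±1.5 σ (preserving the group mean while keeping every walk
  above the detector's 0.6 s separation floor); within-walk jitter is 5 %
  per cycle. Freeze gaps split the walk into bouts re-spaced so a stride
  lands exactly on each gap boundary. When a target mean absolute
  acceleration is requested, the noise-free pulse train is rescaled by
  Brent root finding through the same conditioning the extractor applies,
  then noise (SD 0.2 m/s²) is added; the residual interaction of noise with
  the magnitude conditioning biases the extracted value by about
  −0.1 m/s², inside all stated tolerances.
* **Turning**: a yaw-rate plateau of 360°/duration with one Gaussian step
  pulse per pivot step, pulses at the centres of equal sub-intervals so the
  extractor's padded active duration equals the true duration exactly.
* **Cohort**: 40 subjects with Hoehn & Yahr stages 6/13/12/9 over 1–4,
  9 freezing-of-gait subjects and 11 with other gait difficulty (20 with
  gait item ≥ 2), matching the published composition. UPDRS items are drawn
  from a discretized Gaussian centred at stage−1 (SD 0.6), minimally
  nudged to hit the published group sizes and to keep ≥ 5 subjects per
  detector class (the stratified-CV precondition). Per-subject walking and
  turning parameters are drawn from the published group distributions
  (e.g. CT 1.1 ± 0.32 s vs 1.22 ± 0.49 s; TURN_SP 79.1 ± 8.49 vs
  53.7 ± 6.98 °/s), truncated at ±1.5–2 σ.

What the generator does *not* emulate: axis-resolved limb kinematics and
gravity re-orientation during movement, non-Gaussian sensor noise, tremor
harmonics, swing/stance sub-structure within a stride, and any overlap
between symptom axes beyond the stage→item coupling. Passing tests
therefore demonstrate correctness of the signal processing, feature
definitions and evaluation protocol under controlled morphologies — not
clinical performance on real patients, whose class overlap is certainly
larger than the synthetic cohort's.

## Numerical choices and degenerate inputs

Zero-phase filtering uses second-order sections with even-reflection
padding (short records). Welch FFT length is padded to ≥ 4 s of samples so
the grid is ≤ 0.25 Hz even for 2 s inputs. Band integrals interpolate the
density at band edges. The stance lobe of a simulated stride can fold in
the magnitude series when it exceeds g; the folded bump always lies within
0.6 s of the larger swing peak and is removed by the peak detector's
minimum-distance rule. Degenerate inputs fail loudly with typed errors:
empty series, cutoff ≥ Nyquist, single-class labels, constant regression
targets, fewer than two stride events, no turn steps, classes too small to
stratify.

## Problem sizes

The bundled experiments run at the study's own scale: one 40-subject
cohort (3 recordings each, ≤ 2000 samples per recording) for the model
metrics, 200 walks / 200 turns / 500 turns for the parameter-recovery
means, and 2 s–60 s series for the analytic oracles. A full pipeline run
completes in a few seconds on one CPU.

## Known limitations

Stride length is course-length arithmetic, not inertial dead reckoning, so
it is only meaningful on a fixed course. `SP` (distance / ambulation time)
systematically exceeds `SL/CT` by n/(n−1) because the ambulation window
spans n−1 intervals between n strides; the two agree within the 25 %
coherence band for realistic stride counts. The freeze threshold (1.5 s)
can flag very slow strides in severe gait impairment as freezes; it is
configurable. Severity regressors are trained on 40 subjects and inherit
the small-sample variance the original study reports.
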