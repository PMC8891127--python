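# Methods

This note documents the model implemented by `sts_sonify`, the
assumptions behind it, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## Body model and kinematics

The sit-to-stand (STS) transfer is approximated by a three-segment rigid
body in the sagittal plane: shank, thigh and HAT (head-arms-trunk as one
segment), linked by frictionless pin joints (ankle, knee, hip), with
ground contact only at the distal shank.  Motion is assumed symmetric in
the frontal plane; mediolateral asymmetry (common in hemiparetic
patients) is out of scope.

Coordinates are body-length units with the origin at the ankle, y up and
x forward; unit distance equals body height with knees and hips extended.
Segment CoMs follow `x = x_joint + sin θ · L · D`,
`y = y_joint + cos θ · L · D`, joints are accumulated bottom-up, and the
body CoM is the weighted sum of segment CoMs with mass fractions
renormalized over the three modeled segments (feet and separately
articulated arms are not modeled; renormalization keeps the CoM a convex
combination, hence `y_CoM ≤ 1`).

The default anthropometric table (editable via `anthropometry.*` config
keys) uses classic normative values: segment lengths 0.246 / 0.245 /
0.509 of stature (the HAT value chosen so the extended chain spans
exactly one body length), CoM locations 0.567 / 0.567 / 0.374 of segment
length from the distal joint, and mass fractions 0.093 / 0.200 / 0.678.

Distance from stand, `d = ‖stand − CoM‖ / ‖stand − sit‖`, is left
unclipped in the kinematics layer (sit-back overshoots carry
information, e.g. P3's oscillations); the mapping layer's clipped
transfer is what bounds the sound parameters.

## Sensor model and fusion

Sensor convention per segment: x forward, z along the segment, y the
pitch axis; the pitch gyro reads `+dθ/dt` for increasing forward lean and
a stationary upright sensor reads (0, 0, +g), g = 9.81 m/s².  The
synthetic inverse model projects gravity into the rotating frame and by
default omits the sensor's own linear acceleration, matching the
quasi-static assumption of the accelerometer correction; an
`include_linear_accel` switch adds it (sensor at segment midpoint) so the
robustness of fusion to that assumption can be probed.

Preprocessing is per axis: mean-subtraction over a 10 s stationary window
(for the accelerometer, after removing the projected 1 g gravity vector
along the normalized mean direction), then a 3-point sliding median
(edge-replicated).  Orientation uses the 6-axis (magnetometer-free)
Madgwick gradient-descent filter at its documented optimal gain
β = 0.033; sagittal pitch is magnetometer-independent, so dropping the
magnetometer loses nothing the features need.  The quaternion is
initialized from the first accelerometer sample's gravity direction,
removing the settling transient for short traces.  A zero-norm
accelerometer sample skips the correction step (gyro-only update) and is
logged.  No drift correction beyond the filter itself is attempted; on
the 8 s traces used here the noiseless round trip
(motion → IMU → fusion) recovers angles with RMSE ≤ 0.24°.

## Movement features

All differentiation is first-order backward difference (causal, as a
streaming implementation would be); filters are causal Butterworth with
state initialized from the first sample to suppress the startup step
transient.

* **CoM speed** [bodylengths/s]: norm of the differentiated CoM
  coordinates, then smoothed at 2 Hz before mapping.  The smoothing
  step is part of the model; the cutoff is a package default (the speed
  content of STS is below ~2 Hz, and the 0.45-power pressure transfer
  amplifies any residual differentiation noise).
* **Hip angular velocity**: `|d/dt(θ_HAT − θ_thigh)|`.  The relative
  joint-angle convention is a declared choice (a trunk-only definition
  would be the alternative); it is isolated in one function so it can be
  swapped.
* **Freeze detection**: hip velocity smoothed with a 2nd-order
  Butterworth at 7 Hz, compared to a velocity threshold (default
  8 deg/s); an event fires when the sub-threshold dwell first reaches
  130 ms, one event per episode.  The detector re-arms only once the
  smoothed velocity exceeds the threshold by a hysteresis margin
  (default 50%); without it, sensor noise flickering across the
  threshold during a slow approach splits one stoppage into several
  events.  Setting `rearm_fraction: 0` recovers the plain
  exceed-to-re-arm rule.  The threshold default sits above the
  rectified-noise floor of the fused velocity (~3–5 deg/s under the
  default sensor noise) and far below peak rise velocity (~38 deg/s);
  it was calibrated once against the synthetic patterns and is flagged
  `implementation-default` in the shipped config.
* **Shank angular jerk** [deg/s³]: per-axis double difference of the
  shank gyro (optionally pre-smoothed at 15 Hz — double differencing
  amplifies white sensor noise by fs², so some band-limiting is
  required at 100 Hz), Euclidean norm across axes, with rising
  threshold crossings reported.  Angular jerk is used instead of
  accelerometer-based linear jerk to avoid the gravitational component.

Feature extraction reports freeze events as *movement stoppages*:
episodes that begin before movement onset (first threshold exceedance)
are dropped — the quiet sitting at trial start would otherwise ring the
bell at t ≈ 0.13 s in every clip — and events closer than 0.5 s count
once.  The raw `detect_freezes` operation is unfiltered and usable on
any velocity series.

## Mapping layer

The four transfers follow the table in the README.  Additional choices:

* Note thresholds are equally spaced on the transformed (0.75-power)
  distance; a `calibrated-equal-time` spacing strategy is the natural
  extension but equal spacing is the default.
* The pitch quantizer carries a half-step hysteresis (pitch is
  deliberately unsmoothed, and postural sway would otherwise chatter at
  bin edges).  Descending notes are permitted when `d` increases.
* CoM-speed bounds for the pressure mapping: `speed_hi = 0.5` bl/s
  (maximum intensity; ~P2's fast-rise peak) and `speed_lo = 0.03` bl/s
  (noise gate so the instrument is genuinely silent at rest).
* Jerk overshoot normalization: ceiling defaults to 4x the jerk
  threshold.
* Control rate equals the sensor rate (100 Hz); the 6 Hz and 19 Hz
  parameter smoothers are one-pole filters at that rate.
* Parameter combinations neutralize absent mappings (pitch held at the
  tonic without P, multiplier 1 without J, no bell without F); S is
  always present because it gates audibility.

## Synthesis

The flute is an additive bank of 8 harmonics with geometric rolloff 0.5
plus breath noise (2nd-order lowpass at 2.5 kHz, level tied to
pressure); at the top of the melodic range with multiplier 1 at least
90% of the energy lies below 3 kHz, keeping the perceptually sensitive
2–5 kHz band free for the flexible component.  Phase is accumulated
per sample (note and multiplier changes are click-free) and amplitude is
slew-limited (full scale in 20 ms).  Harmonics that a large pitch
multiplier would push past Nyquist are dropped and the event logged.

The bell is a modal strike — partial ratios 0.5 / 1 / 1.2 / 1.5 / 2 /
2.67 / 3 / 3.56 on a 1250 Hz prime with exponential decays ≤ 0.45 s —
preceded by a short band-limited (2–5 kHz) clang transient.  The clang
is what makes the strike spectrally flat relative to the harmonic flute;
the tail falls below −60 dBFS within the configured 4 s.  These voices
satisfy the model's spectral contracts with plain additive/modal
synthesis; they are not waveguide physical models, and no claim depends
on a specific excitation mechanism.

Clips are mixed, peak-normalized to −1 dBFS and written as 8 s,
48 kHz / 24-bit stereo WAV via 3-byte little-endian packing; output
bytes are a pure function of the control streams and configuration.

## Synthetic movement generator

The generator exists because the study's movement materials (recordings
of one healthy individual) are not deposited; it emulates the *structure*
of the six classes, not any specific subject.

A single rise-progress variable p(t) ∈ [0,1] (minimum-jerk quintic over
the rise interval) drives all three segments: the hip angle
(θ_HAT − θ_thigh) is linear in p — making hip angular velocity vanish
only where the movement genuinely stops — the thigh leaves the seat at
p = 0.2 via a slope-matched quadratic-in-p profile (which makes the HAT
inclination provably monotone after peak trunk flexion, ~35°), and the
shank eases to vertical with a small forward excursion.  Pattern
structure:

* **P2**: time-warp `p = s(τ^2)` — slow bend, fast rise.
* **P3**: pre-rise trunk flexion/extension cycles (sin² bumps, default
  2 × 1.5 s, 30°) and a fast-start rise (warp exponent 0.5; the final
  successful attempt launches with momentum, and a minimum-jerk start
  after the oscillations would itself dwell below the freeze threshold
  long enough to fake a stoppage).
* **P4**: the rise is split into equal sub-rises separated by
  `n_pauses` plateaus of `pause_dwell` (defaults 3 × 0.4 s, ≥ 0.13 s
  enforced so the detector can see them).
* **P5/P6/P3**: band-limited (5–15 Hz) angular perturbation added to the
  shank only (the jerk feature reads the shank gyro; the hip-velocity
  channel stays clean), Tukey-tapered inside the pattern's designated
  window (entire rise / post-rise / pre-rise), scaled to an RMS
  angular-velocity amplitude of 30–40 deg/s.

Defaults (8 s clips, 100 Hz, sitting posture 10°/90°/5°, standing 0°,
default sensor noise 0.05 m/s² and 0.2 deg/s per axis) are the shipped
study conditions; every default is provenance-tagged in
`sts_sonify/defaults.yaml`.

**What the generator does not emulate** — and hence what passing tests do
not show: biofidelic pathology (real impaired STS is less clear-cut,
mixing impairments), frontal-plane motion, soft-tissue and mounting
artifacts, magnetometer disturbance, and between-subject anthropometric
variation.  Tests on these materials validate the *pipeline's contracts*
(recovery accuracy, detector semantics, mapping ranges, spectral
behavior), not clinical classification performance.

## Experiment measures

The metrics module reproduces the evaluation arithmetic: per-block
schedules (6 combos Latin-square counterbalanced across participants ×
6 patterns × 3 repetitions = 108 trials; 25 participants → 2700
records; within-block orders reject identical consecutive patterns),
accuracy (% correct), per-class precision/recall/F-score with the
guarded F = 0 convention, and 6×6 confusion matrices (rows = true).
The human listening results themselves (accuracy ≈ 72% overall, learning
effects, ANOVA statistics) are outcomes of a perception experiment and
are not reproducible computationally; only chance level (100/6 %) and
the design arithmetic are asserted.

## Numerical and testing notes

* Determinism: every stochastic stage takes an explicit seed; renders
  are byte-identical across reruns.
* Problem sizes: tests use single 8 s traces at 100 Hz, 1000-triple
  kinematics oracles, a 10⁵-trial chance-level simulation and a handful
  of audio renders — the whole suite runs in well under a minute.
* The freeze-dwell sweep in `scripts/acceptance.py` dips from twice the
  threshold to zero so the dip is centred on the threshold: the causal
  smoothing filter then delays entry and exit crossings equally and the
  measured minimum registering dwell equals the configured 130 ms
  exactly.
* The Madgwick implementation is cross-checked in the test suite against
  an independent term-by-term transcription of the published algorithm;
  the kinematics against a complex-phasor forward-kinematics oracle; the
  jerk magnitude against the `A(2πf)²` closed form.

## Known limitations

* Madgwick fusion drifts over long captures; nothing beyond the filter's
  own correction is implemented (8 s traces make this negligible here).
* The hip-angle definition (relative HAT-thigh) is a convention; other
  definitions shift the freeze threshold's meaning.
* The melody accelerates near standing because note thresholds are
  equally spaced on transformed distance while the CoM decelerates; the
  alternative spacing strategy is noted in the mapping layer but not the
  default.
* Empirical thresholds were calibrated against the synthetic patterns;
  recorded human data would require recalibration (they are single
  config keys).
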