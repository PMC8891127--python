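# sts-sonify

An offline, testable implementation of a sonification model for the
sit-to-stand (STS) transfer — the everyday movement of rising from a
chair, whose quality degrades with age, stroke, Parkinson's disease and
orthopedic impairment.  The package turns tri-segment inertial recordings
(or synthetic equivalents) into sound a clinician or patient can
interpret: the body's rise becomes an ascending flute melody, movement
energy becomes loudness, stoppages ring a bell, and jerkiness glitches
the pitch.

It is written for movement-science and auditory-display researchers who
want to analyze STS inertial data, regenerate stimulus clips, or extend
the mapping model, entirely from Python (a thin `sts` command-line front
end covers the shell workflows).

## The model

**Capture.** Three IMUs (100 Hz accelerometer + gyroscope) on shank,
thigh and HAT (head-arms-trunk).  Per axis: bias compensation over a 10 s
stationary window (accounting for gravity), a 3-point median filter, then
6-axis Madgwick gradient-descent fusion (gain β = 0.033) yielding each
segment's anteroposterior inclination θ (0° vertical, + forward).

**Kinematics.** With the origin at the distal shank and body height = 1,
each segment CoM is

    x_seg = x_joint + sin(θ_seg) · L_seg · D_CoM
    y_seg = y_joint + cos(θ_seg) · L_seg · D_CoM

and the body CoM is the mass-fraction-weighted sum over the three
segments (normative anthropometric table, editable in config).  STS
progression is the normalized distance from stand

    d = ‖stand − CoM‖ / ‖stand − sit‖   (1 at sitting, 0 standing),

with sit/stand CoM coordinates calibrated from quiet postures.

**Features → sound (the four mappings).**

| id | feature | parameter | range | polarity | order | smoothing |
|----|---------|-----------|-------|----------|-------|-----------|
| S  | CoM speed        | flute blowing pressure | 0–1      | + | 0.45 | 6 Hz |
| P  | distance d       | flute melodic pitch    | A4–A5    | − | 0.75 | none |
| F  | freeze events    | bell strike            | off–on   | + | 1    | none |
| J  | shank jerk       | pitch multiplier       | 1–10     | + | 0.45 | 19 Hz |

Each transfer is `param = min + (max−min)·u^order` on the clipped,
normalized (and for `−` polarity, inverted) feature.  Pitch is quantized
onto the eight tones of a one-octave A-major scale.  A *freeze* is
registered when hip angular velocity (7 Hz 2nd-order Butterworth
smoothed) stays below an empirically set threshold for ≥ 130 ms; shank
jerk is the Euclidean norm of the double-differentiated gyro vector.
Subsets of the mappings form the six parameter combinations
S, SJ, SP, SJF, SPF, SJPF used to build stimulus sets.

**Synthesis.** An additive-harmonic flute with breath noise (≥ 90% of its
energy below 3 kHz at the top of the melodic range, leaving 2–5 kHz free)
and a modal bell (inharmonic decaying partials plus a broadband clang)
are mixed, peak-normalized to −1 dBFS and written as 8 s, 48 kHz / 24-bit
stereo WAV clips — byte-identical across reruns for the same config and
seed.

**Synthetic movement.** Because no recordings are deposited, the
`simulate` module generates the six study pattern classes — P1 slow rise,
P2 slow-bend/fast-rise, P3 failed attempts, P4 freezing, P5 jerky rise,
P6 unstable ankles — as minimum-jerk segment trajectories with
pattern-specific time-warping, pauses, pre-rise trunk oscillations and
band-limited (5–15 Hz) shank perturbation, plus the inverse sensor model
(gravity projection + noise + bias) so the whole pipeline is testable
end to end.

## Worked example

`examples/03_movement_features.py` contrasts a freeze-ridden rise (P4)
with a jerky one (P5):

```
P4: peak CoM speed 0.43 bl/s, d range 0.00..1.16
    freezes at [2.08 3.55 5.04 6.51] s, 0 jerk crossings
P5: peak CoM speed 0.33 bl/s, d range 0.00..1.17
    freezes at [5.15] s, 33 jerk crossings
```

P4's three mid-rise pauses plus its terminal stop produce four bell
strikes and no pitch glitches; P5 produces a single terminal bell but 33
jerk-threshold crossings that modulate the flute pitch throughout the
rise — the two channels a listener uses to tell the classes apart.
`examples/02_fuse_and_reconstruct.py` shows the sensor-fusion round trip
(`noiseless: RMSE [deg] shank=0.039 thigh=0.231 hat=0.138`), and
`examples/05_experiment_metrics.py` reproduces the experiment arithmetic
(108 trials/participant, 2700 records for 25 participants, 16.67%
6-alternative chance level).

The same workflows are available from the shell:

```bash
sts simulate --pattern P4 --seed 7 --out out/
sts features out/P4_imu.csv --out features.csv
sts sonify out/P4_imu.csv --combo SJPF --out clip.wav
sts batch --seed 1 --instances 3 --out stimuli/   # full 6x6x3 set
sts metrics responses.csv --by combo
```

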