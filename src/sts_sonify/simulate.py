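"""Synthetic sit-to-stand (STS) motion and inertial-data generation.

Recorded inertial data for the six STS movement classes is not deposited
anywhere, so every downstream stage of the pipeline is exercised against
synthetic traces generated here.  The six classes are:

====  =================  =======================================================
id    name               structure
====  =================  =======================================================
P1    Slow rise          uniform-speed rise, stops once after the rise
P2    Slow - fast        slow trunk bend, fast rise (time-warped progress)
P3    Failed attempts    pre-rise trunk flexion/extension cycles, jerky pre-rise
P4    Freezing           multiple pauses (plateaus) during the rise
P5    Jerky rise         band-limited angular perturbation throughout the rise
P6    Unstable ankles    uniform rise, perturbation after the rise
====  =================  =======================================================

The baseline trajectory is built from a single minimum-jerk "rise
progress" variable p(t) in [0, 1].  All three segment angles are smooth
functions of p, with the hip angle (theta_hat - theta_thigh) monotone in
p — so hip angular velocity vanishes only where the movement genuinely
stops (before onset, during P4 plateaus, and at completion), which is what
the downstream freeze detector keys on.  Pattern structure is imposed by
time-warping p (P2), inserting plateaus into p (P4), adding pre-rise trunk
oscillation cycles (P3), and adding band-limited (5-15 Hz) angular
perturbation to the shank in a pattern-specific window (P3/P5/P6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt, windows

from .traces import GRAVITY, ImuTrace, MotionTrace

PATTERN_IDS = ("P1", "P2", "P3", "P4", "P5", "P6")

PATTERN_NAMES = {
    "P1": "Slow rise",
    "P2": "Slow - fast",
    "P3": "Failed attempts",
    "P4": "Freezing",
    "P5": "Jerky rise",
    "P6": "Unstable ankles",
}

JERK_WINDOWS = ("none", "pre_rise", "whole", "post_rise")


def minimum_jerk(u):
    """Minimum-jerk (quintic) ease 10u^3 - 15u^4 + 6u^5 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


@dataclass
class PostureConfig:
    """Segment inclinations (deg) at calibrated sitting and standing.

    ``flexion_total`` is the sitting hip angle magnitude
    |sit_hat - sit_thigh| traversed during the rise; ``seatoff_progress``
    is the rise-progress fraction before which the thigh stays on the
    seat; ``shank_lean`` is a small forward shank excursion around
    seat-off.
    """

    sit_shank: float = 10.0
    sit_thigh: float = 90.0
    sit_hat: float = 5.0
    stand_shank: float = 0.0
    stand_thigh: float = 0.0
    stand_hat: float = 0.0
    seatoff_progress: float = 0.2
    shank_lean: float = 4.0


@dataclass
class PatternSpec:
    """Parameters describing one synthetic STS pattern instance."""

    pattern_id: str
    total_duration: float = 8.0
    rise_onset: float = 1.5
    rise_duration: float = 4.0
    n_pauses: int = 0
    pause_dwell: float = 0.0
    pre_rise_oscillations: int = 0
    oscillation_period: float = 1.5
    oscillation_amplitude: float = 30.0
    time_warp: float = 1.0
    jerk_amplitude: float = 0.0
    jerk_window: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pattern_id not in PATTERN_IDS:
            raise ValueError(f"invalid pattern_id {self.pattern_id!r}")
        if self.jerk_window not in JERK_WINDOWS:
            raise ValueError(f"invalid jerk_window {self.jerk_window!r}")
        if not (self.total_duration > self.rise_onset + self.rise_duration >= 0):
            raise ValueError(
                "need total_duration > rise_onset + rise_duration >= 0"
            )
        if self.pattern_id == "P4":
            if self.n_pauses < 2:
                raise ValueError("P4 requires n_pauses >= 2")
            if self.pause_dwell < 0.13:
                raise ValueError("P4 requires pause_dwell >= 0.13 s")
            if self.n_pauses * self.pause_dwell >= self.rise_duration:
                raise ValueError(
                    "rise_duration too short to fit "
                    f"{self.n_pauses} pauses of {self.pause_dwell} s"
                )
        if self.pattern_id in ("P1", "P2") and self.jerk_amplitude != 0:
            raise ValueError("P1/P2 must have jerk_amplitude = 0")
        expected_window = {"P3": "pre_rise", "P5": "whole", "P6": "post_rise"}
        if self.pattern_id in expected_window:
            if self.jerk_window != expected_window[self.pattern_id]:
                raise ValueError(
                    f"{self.pattern_id} requires jerk_window = "
                    f"{expected_window[self.pattern_id]!r}"
                )
        if self.pattern_id == "P3":
            if self.pre_rise_oscillations < 1:
                raise ValueError("P3 requires pre_rise_oscillations >= 1")
            span = self.pre_rise_oscillations * self.oscillation_period
            if span > self.rise_onset:
                raise ValueError(
                    "rise_onset too early to fit pre-rise oscillations"
                )

    @property
    def rise_end(self) -> float:
        return self.rise_onset + self.rise_duration

    def jerk_window_bounds(self) -> tuple:
        """(t0, t1) seconds within which jerk perturbation is injected."""
        if self.jerk_window == "pre_rise":
            t0 = self.rise_onset - self.pre_rise_oscillations * self.oscillation_period
            return (max(0.3, t0), self.rise_onset)
        if self.jerk_window == "whole":
            return (self.rise_onset, self.rise_end)
        if self.jerk_window == "post_rise":
            return (self.rise_end, self.total_duration - 0.3)
        return (0.0, 0.0)


def default_pattern_specs(seed: int = 0) -> dict:
    """The six study patterns with their default structural parameters.

    The per-pattern seeds are derived from ``seed`` so that instances of
    different patterns use independent perturbation streams.
    """
    base = dict(total_duration=8.0)
    specs = {
        "P1": PatternSpec("P1", rise_onset=1.5, rise_duration=4.0, **base),
        "P2": PatternSpec(
            "P2", rise_onset=1.0, rise_duration=5.0, time_warp=2.0, **base
        ),
        "P3": PatternSpec(
            "P3",
            rise_onset=4.0,
            rise_duration=2.5,
            pre_rise_oscillations=2,
            oscillation_period=1.5,
            oscillation_amplitude=30.0,
            time_warp=0.5,  # the final successful rise launches fast
            jerk_amplitude=30.0,
            jerk_window="pre_rise",
            **base,
        ),
        "P4": PatternSpec(
            "P4",
            rise_onset=1.0,
            rise_duration=5.5,
            n_pauses=3,
            pause_dwell=0.4,
            **base,
        ),
        "P5": PatternSpec(
            "P5",
            rise_onset=1.5,
            rise_duration=4.0,
            jerk_amplitude=40.0,
            jerk_window="whole",
            **base,
        ),
        "P6": PatternSpec(
            "P6",
            rise_onset=1.0,
            rise_duration=3.0,
            jerk_amplitude=40.0,
            jerk_window="post_rise",
            **base,
        ),
    }
    return {
        pid: replace(spec, seed=seed * 101 + i)
        for i, (pid, spec) in enumerate(specs.items())
    }


def _rise_progress(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    """Monotone rise progress p(t) in [0, 1] with warp / plateaus."""
    tau = np.clip((t - spec.rise_onset) / spec.rise_duration, 0.0, 1.0)
    if spec.n_pauses > 0:
        k = spec.n_pauses
        hold = spec.pause_dwell / spec.rise_duration
        move = 1.0 - k * hold          # validated > 0
        sub = move / (k + 1)           # normalized duration of each sub-rise
        p = np.zeros_like(tau)
        for i in range(k + 1):
            start = i * (sub + hold)
            u = (tau - start) / sub
            p = p + minimum_jerk(u) / (k + 1)
        return p
    return minimum_jerk(np.power(tau, spec.time_warp))


def _oscillation(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    """Pre-rise trunk flexion/extension cycles (deg added to theta_hat)."""
    if spec.pre_rise_oscillations <= 0:
        return np.zeros_like(t)
    span = spec.pre_rise_oscillations * spec.oscillation_period
    start = spec.rise_onset - span
    c = (t - start) / spec.oscillation_period
    active = (c >= 0) & (c <= spec.pre_rise_oscillations)
    osc = np.where(active, np.sin(np.pi * c) ** 2, 0.0)
    return spec.oscillation_amplitude * osc


def _jerk_perturbation(spec: PatternSpec, t: np.ndarray, fs: float) -> np.ndarray:
    """Band-limited (5-15 Hz) angular perturbation (deg) for the shank.

    Scaled so that the RMS angular-velocity of the perturbation inside the
    active window equals ``spec.jerk_amplitude`` (deg/s), then tapered with
    a Tukey window so the trace stays smooth at the window edges.
    """
    if spec.jerk_amplitude <= 0 or spec.jerk_window == "none":
        return np.zeros_like(t)
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(len(t))
    lo, hi = 5.0, 15.0
    b, a = butter(3, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    band = filtfilt(b, a, white)
    t0, t1 = spec.jerk_window_bounds()
    mask = (t >= t0) & (t <= t1)
    n_active = int(mask.sum())
    if n_active < 8:
        return np.zeros_like(t)
    taper = np.zeros_like(t)
    taper[mask] = windows.tukey(n_active, alpha=0.3)
    shaped = band * taper
    vel = np.gradient(shaped, 1.0 / fs)
    rms = float(np.sqrt(np.mean(vel[mask] ** 2)))
    if rms == 0.0:
        return np.zeros_like(t)
    return shaped * (spec.jerk_amplitude / rms)


def generate_motion(
    spec: PatternSpec,
    posture: PostureConfig | None = None,
    fs: float = 100.0,
) -> MotionTrace:
    """Generate segment-angle trajectories for one STS pattern instance.

    The trajectory starts at the sitting posture, rises to standing over
    ``[rise_onset, rise_onset + rise_duration]`` and holds standing until
    ``total_duration``.  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    posture = posture or PostureConfig()
    n = int(round(spec.total_duration * fs))
    t = np.arange(n) / fs
    p = _rise_progress(spec, t)
    s = p  # progress is already minimum-jerk shaped

    # Thigh: on the seat until seat-off progress, then driven to standing
    # by a quadratic-in-progress profile.  The quadratic joins the seat
    # phase with matched (zero) slope at seat-off; smoothness of the stop
    # at completion comes from the progress variable itself (p'(t) -> 0).
    # Together with the linear-in-progress hip angle this makes the HAT
    # inclination decrease monotonically after peak trunk flexion.
    q = np.clip(
        (p - posture.seatoff_progress) / (1.0 - posture.seatoff_progress), 0.0, 1.0
    )
    theta_thigh = posture.sit_thigh + (
        posture.stand_thigh - posture.sit_thigh
    ) * q**2

    # Hip angle (hat - thigh) is monotone in progress: eased from its
    # sitting value to its standing value, so hip angular velocity only
    # vanishes where the movement stops.
    hip_sit = posture.sit_hat - posture.sit_thigh
    hip_stand = posture.stand_hat - posture.stand_thigh
    hip = hip_sit + (hip_stand - hip_sit) * s
    theta_hat = theta_thigh + hip + _oscillation(spec, t)

    # Shank: eased to standing with a small forward excursion at seat-off.
    theta_shank = (
        posture.sit_shank
        + (posture.stand_shank - posture.sit_shank) * s
        + posture.shank_lean * np.sin(np.pi * p) ** 2
        + _jerk_perturbation(spec, t, fs)
    )

    return MotionTrace(
        fs=fs,
        theta_shank=theta_shank,
        theta_thigh=theta_thigh,
        theta_hat=theta_hat,
    )


@dataclass
class ImuNoiseModel:
    """Sensor imperfections applied when deriving inertial signals."""

    accel_noise_sd: float = 0.0   # m/s^2, per axis
    gyro_noise_sd: float = 0.0    # deg/s, per axis
    accel_bias: tuple = (0.0, 0.0, 0.0)   # m/s^2
    gyro_bias: tuple = (0.0, 0.0, 0.0)    # deg/s

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def motion_to_imu(
    trace: MotionTrace,
    noise: ImuNoiseModel | None = None,
    seed: int = 0,
    include_linear_accel: bool = False,
    segment_lengths: dict | None = None,
    body_height: float = 1.7,
) -> ImuTrace:
    """Derive per-segment inertial signals from a motion trace.

    Per segment: the pitch-axis gyro reads ``+d(theta)/dt``; the
    accelerometer reads gravity projected into the rotating sensor frame,
    ``(g sin(theta), 0, g cos(theta))``.  With ``include_linear_accel``
    the specific force additionally contains the sensor's own linear
    acceleration (sensor placed at the segment midpoint on the kinematic
    chain, scaled by ``body_height``); the default omits it, matching the
    quasi-static assumption of the accelerometer correction in the
    fusion filter.  Deterministic for fixed ``seed``.
    """
    noise = noise or ImuNoiseModel()
    rng = np.random.default_rng(seed)
    dt = 1.0 / trace.fs

    lin = {}
    if include_linear_accel:
        from .kinematics import Anthropometry

        fractions = segment_lengths or {
            s: getattr(Anthropometry(), s).L for s in ("shank", "thigh", "hat")
        }
        # World-frame position of each segment midpoint, metres.
        ankle = np.zeros((len(trace), 2))
        pos = {}
        joint = ankle
        for seg in ("shank", "thigh", "hat"):
            th = np.radians(trace.angle(seg))
            L = fractions[seg] * body_height
            vec = np.column_stack([np.sin(th), np.cos(th)]) * L
            pos[seg] = joint + 0.5 * vec
            joint = joint + vec
        for seg, pw in pos.items():
            ax_w = np.gradient(np.gradient(pw[:, 0], dt), dt)
            az_w = np.gradient(np.gradient(pw[:, 1], dt), dt)
            lin[seg] = (ax_w, az_w)

    data = {}
    for seg in ("shank", "thigh", "hat"):
        th = np.radians(trace.angle(seg))
        omega = np.gradient(trace.angle(seg), dt)  # deg/s
        n = len(trace)
        fx_w = np.zeros(n)
        fz_w = np.full(n, GRAVITY)
        if include_linear_accel:
            fx_w = fx_w + lin[seg][0]
            fz_w = fz_w + lin[seg][1]
        # Project world specific force into the sensor frame (forward-lean
        # convention: ax = g sin(theta) for a static tilted sensor).
        ax = np.cos(th) * fx_w + np.sin(th) * fz_w
        az = -np.sin(th) * fx_w + np.cos(th) * fz_w
        block = np.column_stack(
            [
                ax + noise.accel_bias[0],
                np.full(n, noise.accel_bias[1]),
                az + noise.accel_bias[2],
                np.full(n, noise.gyro_bias[0]),
                omega + noise.gyro_bias[1],
                np.full(n, noise.gyro_bias[2]),
            ]
        )
        if noise.accel_noise_sd > 0:
            block[:, :3] += rng.normal(0.0, noise.accel_noise_sd, (n, 3))
        if noise.gyro_noise_sd > 0:
            block[:, 3:] += rng.normal(0.0, noise.gyro_noise_sd, (n, 3))
        data[seg] = block

    return ImuTrace(fs=trace.fs, data=data)
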