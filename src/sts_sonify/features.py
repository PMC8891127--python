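"""The four sonified movement features.

From the reconstructed body state and the raw gyro stream, four features
drive the sonification at the control (= sensor) rate:

* **CoM speed** [bodylengths/s] — Euclidean norm of the singly
  differentiated CoM coordinates.
* **Distance from stand** ``d`` — computed in :mod:`sts_sonify.kinematics`.
* **Freeze events** — hip angular velocity is smoothed with a causal
  2nd-order Butterworth lowpass (fc = 7 Hz) and compared to an
  empirically set threshold; a freeze is registered once the velocity has
  stayed below the threshold for a sustained dwell of 130 ms or longer.
  One event per sub-threshold episode (no re-trigger until the signal
  exceeds the threshold again).  Movement completion naturally produces a
  terminal event in freeze-free STS.
* **Shank angular jerk** [deg/s^3] — the gyro angular-velocity vector is
  double-differentiated per axis; the Euclidean norm across axes is the
  feature.  Angular (not linear) jerk avoids the gravitational component
  that contaminates accelerometer-based jerk.

Differentiation is first-order backward difference throughout: causal,
matching what a streaming implementation would do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, lfilter_zi


@dataclass
class FreezeConfig:
    lowpass_order: int = 2
    lowpass_fc: float = 7.0          # Hz
    velocity_threshold: float = 8.0  # deg/s, empirically set vs. the simulator
    min_dwell: float = 0.130         # s
    rearm_fraction: float = 0.5      # hysteresis: re-arm above thr*(1+frac)

    def __post_init__(self) -> None:
        if self.min_dwell <= 0:
            raise ValueError("min_dwell must be positive")
        if self.lowpass_fc <= 0:
            raise ValueError("lowpass_fc must be positive")


@dataclass
class JerkConfig:
    jerk_threshold: float = 20000.0  # deg/s^3, empirically set vs. the simulator
    smoothing_fc: float | None = 15.0  # pre-differentiation gyro lowpass, Hz

    def __post_init__(self) -> None:
        if self.jerk_threshold <= 0:
            raise ValueError("jerk_threshold must be positive")


def _backward_diff(x: np.ndarray, fs: float) -> np.ndarray:
    """First-order backward difference; first sample duplicated."""
    x = np.asarray(x, dtype=float)
    d = np.empty_like(x)
    d[1:] = np.diff(x) * fs
    d[0] = d[1] if len(x) > 1 else 0.0
    return d


def com_speed(x_com, y_com, fs: float) -> np.ndarray:
    """Instantaneous CoM speed [bodylengths/s], length-preserving."""
    vx = _backward_diff(x_com, fs)
    vy = _backward_diff(y_com, fs)
    return np.hypot(vx, vy)


def hip_angular_velocity(theta_hat, theta_thigh, fs: float) -> np.ndarray:
    """|d/dt (theta_hat - theta_thigh)| [deg/s].

    The hip joint angle is taken as the relative HAT-thigh inclination;
    this relative-angle convention is a declared package choice, isolated
    here so it can be swapped.
    """
    hip = np.asarray(theta_hat, dtype=float) - np.asarray(theta_thigh, dtype=float)
    return np.abs(_backward_diff(hip, fs))


def _causal_lowpass(x: np.ndarray, fc: float, fs: float, order: int) -> np.ndarray:
    """Causal Butterworth lowpass, state initialized at the first sample."""
    b, a = butter(order, fc / (fs / 2.0), btype="low")
    zi = lfilter_zi(b, a) * x[0]
    y, _ = lfilter(b, a, x, zi=zi)
    return y


def detect_freezes(hip_vel: np.ndarray, fs: float,
                   cfg: FreezeConfig | None = None) -> np.ndarray:
    """Freeze onset times [s] from a hip angular-velocity series.

    The velocity is smoothed (causal Butterworth per ``cfg``), then a
    freeze event is emitted at the instant the sub-threshold dwell first
    reaches ``min_dwell``; one event per sub-threshold episode.  The
    detector re-arms only after the smoothed velocity exceeds the
    threshold by the hysteresis margin ``rearm_fraction`` (0 recovers
    plain exceed-to-re-arm behavior); the margin keeps sensor noise that
    flickers across the threshold during a slow approach from splitting
    one stoppage into several events.
    """
    cfg = cfg or FreezeConfig()
    hip_vel = np.asarray(hip_vel, dtype=float)
    if cfg.lowpass_fc >= fs / 2.0:
        raise ValueError("lowpass_fc must be below the Nyquist frequency")
    smooth = _causal_lowpass(hip_vel, cfg.lowpass_fc, fs, cfg.lowpass_order)

    min_samples = int(np.ceil(cfg.min_dwell * fs))
    rearm_level = cfg.velocity_threshold * (1.0 + cfg.rearm_fraction)
    events = []
    below = 0
    armed = True
    for i, v in enumerate(smooth):
        if v < cfg.velocity_threshold:
            below += 1
            if armed and below >= min_samples:
                events.append(i / fs)
                armed = False
        else:
            below = 0
            if v >= rearm_level:
                armed = True
    return np.asarray(events)


def shank_jerk(gyro_xyz: np.ndarray, fs: float,
               cfg: JerkConfig | None = None) -> tuple:
    """Shank angular-jerk norm [deg/s^3] and threshold-crossing times.

    ``gyro_xyz`` is the (n, 3) shank gyroscope block in deg/s.  Each axis
    is optionally lowpassed (``smoothing_fc``), double-differentiated
    (backward differences), and the Euclidean norm across axes taken.
    Crossing times are where the norm rises through ``jerk_threshold``.

    Returns ``(jerk_norm, crossing_times)``.
    """
    cfg = cfg or JerkConfig()
    g = np.asarray(gyro_xyz, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[0] < 3:
        raise ValueError("need at least 3 samples to double-differentiate")
    if cfg.smoothing_fc is not None:
        g = np.column_stack(
            [_causal_lowpass(g[:, j], cfg.smoothing_fc, fs, 2)
             for j in range(g.shape[1])]
        )
    jerk_axes = np.column_stack(
        [_backward_diff(_backward_diff(g[:, j], fs), fs)
         for j in range(g.shape[1])]
    )
    jerk = np.linalg.norm(jerk_axes, axis=1)
    above = jerk >= cfg.jerk_threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    return jerk, rising / fs


@dataclass
class FeatureFrames:
    """The four features sampled at the control rate."""

    fs: float
    t: np.ndarray
    com_speed: np.ndarray
    d: np.ndarray
    freeze_times: np.ndarray
    jerk: np.ndarray
    jerk_crossings: np.ndarray

    @property
    def freeze_flags(self) -> np.ndarray:
        """Boolean onset-flag series aligned with ``t``."""
        flags = np.zeros(len(self.t), dtype=bool)
        idx = np.round(self.freeze_times * self.fs).astype(int)
        flags[idx[(idx >= 0) & (idx < len(flags))]] = True
        return flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "com_speed": self.com_speed,
                "d": self.d,
                "freeze": self.freeze_flags.astype(int),
                "jerk": self.jerk,
            }
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# units: com_speed bodylengths/s, d unitless, "
                f"freeze onset flag, jerk deg/s^3; fs = {self.fs:g} Hz\n"
            )
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FeatureFrames":
        from .traces import _read_commented_csv

        df, fs = _read_commented_csv(path)
        flags = df["freeze"].to_numpy().astype(bool)
        t = df["t"].to_numpy()
        return cls(
            fs=fs,
            t=t,
            com_speed=df["com_speed"].to_numpy(),
            d=df["d"].to_numpy(),
            freeze_times=t[flags],
            jerk=df["jerk"].to_numpy(),
            jerk_crossings=np.asarray([]),
        )


def extract_features(motion, shank_gyro: np.ndarray, calibration,
                     anthro=None, freeze_cfg: FreezeConfig | None = None,
                     jerk_cfg: JerkConfig | None = None,
                     speed_smoothing_fc: float | None = 2.0,
                     freeze_merge_window: float = 0.5) -> FeatureFrames:
    """Full feature extraction from a MotionTrace + shank gyro block.

    The CoM speed feature is smoothed prior to mapping
    (``speed_smoothing_fc``), taming differentiation noise that the
    low-order power-law pressure transfer would otherwise amplify.
    Freeze events are reported as movement stoppages: episodes before
    movement onset (the first smoothed hip-velocity threshold
    exceedance) are dropped — quietly sitting at trial start is not a
    stoppage *of* the movement — and events closer than
    ``freeze_merge_window`` count once.
    """
    from .kinematics import body_com_trajectory, distance_from_stand

    freeze_cfg = freeze_cfg or FreezeConfig()
    state = body_com_trajectory(motion, anthro)
    speed = com_speed(state.x_com, state.y_com, motion.fs)
    if speed_smoothing_fc:
        speed = _causal_lowpass(speed, speed_smoothing_fc, motion.fs, 2)
    d = distance_from_stand(state.x_com, state.y_com, calibration)
    hip_vel = hip_angular_velocity(motion.theta_hat, motion.theta_thigh,
                                   motion.fs)
    freezes = detect_freezes(hip_vel, motion.fs, freeze_cfg)
    smooth_vel = _causal_lowpass(hip_vel, freeze_cfg.lowpass_fc, motion.fs,
                                 freeze_cfg.lowpass_order)
    above = np.flatnonzero(smooth_vel >= freeze_cfg.velocity_threshold)
    onset = above[0] / motion.fs if len(above) else np.inf
    kept = []
    for t_ev in freezes:
        if t_ev < onset:
            continue
        if kept and t_ev - kept[-1] <= freeze_merge_window:
            continue
        kept.append(float(t_ev))
    jerk, crossings = shank_jerk(shank_gyro, motion.fs, jerk_cfg)
    return FeatureFrames(
        fs=motion.fs,
        t=motion.t,
        com_speed=speed,
        d=d,
        freeze_times=np.asarray(kept),
        jerk=jerk,
        jerk_crossings=crossings,
    )


@dataclass
class PatternSignature:
    """Class-discriminating summary of one trace's features."""

    n_freezes_post_onset: int
    jerk_crossings: np.ndarray
    movement_onset: float


def pattern_signature(features: FeatureFrames, hip_vel: np.ndarray,
                      fs: float, freeze_cfg: FreezeConfig | None = None,
                      merge_window: float = 0.5) -> PatternSignature:
    """Summarize the feature channels that disambiguate the six patterns.

    Freezes are counted from movement onset (the first time the smoothed
    hip velocity exceeds the freeze threshold) so the initial quiet
    sitting episode is not counted as a stoppage *of* the movement, and
    events closer than ``merge_window`` are counted as one stoppage (a
    noisy velocity can chatter around the threshold while coming to
    rest; the distinct plateaus of a freeze-ridden rise are far apart).
    """
    cfg = freeze_cfg or FreezeConfig()
    smooth = _causal_lowpass(np.asarray(hip_vel, dtype=float),
                             cfg.lowpass_fc, fs, cfg.lowpass_order)
    above = np.flatnonzero(smooth >= cfg.velocity_threshold)
    onset = above[0] / fs if len(above) else np.inf
    post = np.sort(features.freeze_times[features.freeze_times >= onset])
    n_post = 0
    last = -np.inf
    for t_ev in post:
        if t_ev - last > merge_window:
            n_post += 1
        last = t_ev
    return PatternSignature(
        n_freezes_post_onset=n_post,
        jerk_crossings=features.jerk_crossings,
        movement_onset=onset,
    )
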