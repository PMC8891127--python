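"""Raw inertial samples -> anteroposterior segment inclination.

Preprocessing follows the capture chain used for the movement features:
per-axis bias compensation from a stationary window (gravity accounted
for on the accelerometer), a 3-point median filter, then 6-axis Madgwick
gradient-descent sensor fusion with the filter gain at its documented
optimum (beta = 0.033).  Only the sagittal (pitch) inclination is
extracted — the feature set needs nothing else, and pitch is independent
of the magnetometer, so the magnetometer-free IMU variant of the filter
is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .traces import GRAVITY, ImuTrace

log = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    beta: float = 0.033            # Madgwick gradient-descent gain
    stationary_window: float = 10.0  # seconds of quiet data for bias estimation
    median_points: int = 3

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.stationary_window <= 0:
            raise ValueError("stationary_window must be positive")
        if self.median_points % 2 != 1:
            raise ValueError("median_points must be odd")


def estimate_bias(accel: np.ndarray, gyro: np.ndarray, fs: float,
                  window: float = 10.0) -> tuple:
    """Per-axis sensor offsets from a stationary segment.

    Gyro offsets are the axis-wise means over the window.  Accelerometer
    offsets are the axis-wise means minus the projected gravity vector,
    with the gravity direction taken as the normalized mean reading and
    magnitude 1 g — so a tilted but stationary sensor yields near-zero
    accelerometer offsets.

    Returns ``(accel_offset, gyro_offset)``, each shape (3,).
    """
    n = int(round(window * fs))
    if n > len(accel) or n > len(gyro):
        raise ValueError("stationary window longer than trace")
    if n < 1:
        raise ValueError("window must contain at least one sample")
    gyro_off = gyro[:n].mean(axis=0)
    accel_mean = accel[:n].mean(axis=0)
    norm = np.linalg.norm(accel_mean)
    if norm == 0:
        raise ValueError("mean accelerometer reading has zero norm")
    accel_off = accel_mean - (accel_mean / norm) * GRAVITY
    return accel_off, gyro_off


def median3(series: np.ndarray, points: int = 3) -> np.ndarray:
    """Sliding odd-length median with edge replication, length-preserving."""
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ValueError("series must contain at least one sample")
    if series.ndim == 1:
        return median_filter(series, size=points, mode="nearest")
    return median_filter(series, size=(points, 1), mode="nearest")


class MadgwickIMU:
    """6-axis (gyro + accel) Madgwick gradient-descent orientation filter.

    The quaternion tracks the sensor frame relative to the world frame;
    each sample applies gyroscope integration plus a gradient-descent step
    (gain ``beta``) toward alignment of the measured accelerometer
    direction with gravity.  A zero-norm accelerometer sample skips the
    correction (gyro-only update).
    """

    def __init__(self, beta: float = 0.033, fs: float = 100.0):
        self.beta = beta
        self.fs = fs
        self.q = np.array([1.0, 0.0, 0.0, 0.0])

    def init_from_accel(self, accel: np.ndarray) -> None:
        """Initialize pitch from one accelerometer sample's gravity direction."""
        ax, _, az = accel
        alpha = np.arctan2(-ax, az)  # internal rotation angle about y
        self.q = np.array([np.cos(alpha / 2), 0.0, np.sin(alpha / 2), 0.0])

    def update(self, gyro_dps: np.ndarray, accel: np.ndarray) -> np.ndarray:
        q0, q1, q2, q3 = self.q
        # Forward-lean pitch-rate convention -> internal right-handed rate.
        gx, gy, gz = np.radians(gyro_dps)
        gy = -gy

        qdot = 0.5 * np.array(
            [
                -q1 * gx - q2 * gy - q3 * gz,
                q0 * gx + q2 * gz - q3 * gy,
                q0 * gy - q1 * gz + q3 * gx,
                q0 * gz + q1 * gy - q2 * gx,
            ]
        )

        norm_a = np.linalg.norm(accel)
        if norm_a > 0.0:
            ax, ay, az = accel / norm_a
            # Objective: rotate world gravity into the sensor frame and
            # match the measured direction.
            f = np.array(
                [
                    2.0 * (q1 * q3 - q0 * q2) - ax,
                    2.0 * (q0 * q1 + q2 * q3) - ay,
                    2.0 * (0.5 - q1 * q1 - q2 * q2) - az,
                ]
            )
            J = np.array(
                [
                    [-2.0 * q2, 2.0 * q3, -2.0 * q0, 2.0 * q1],
                    [2.0 * q1, 2.0 * q0, 2.0 * q3, 2.0 * q2],
                    [0.0, -4.0 * q1, -4.0 * q2, 0.0],
                ]
            )
            grad = J.T @ f
            gnorm = np.linalg.norm(grad)
            if gnorm > 0.0:
                qdot = qdot - self.beta * grad / gnorm
        else:
            log.warning("zero-norm accelerometer sample: gyro-only update")

        self.q = self.q + qdot / self.fs
        self.q = self.q / np.linalg.norm(self.q)
        return self.q

    @property
    def pitch_deg(self) -> float:
        """Sagittal inclination, positive forward lean [deg]."""
        q0, q1, q2, q3 = self.q
        vx = 2.0 * (q1 * q3 - q0 * q2)   # gravity direction in sensor frame
        vz = q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3
        return float(np.degrees(np.arctan2(vx, vz)))


def fuse_inclination(accel: np.ndarray, gyro: np.ndarray, fs: float,
                     cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse one segment's (bias-compensated) samples into inclination [deg].

    Applies the 3-point median filter to every channel, initializes the
    quaternion from the first accelerometer sample's gravity direction,
    then runs the per-sample Madgwick update.  Output has the input
    length.
    """
    cfg = cfg or FusionConfig()
    accel = median3(np.asarray(accel, dtype=float), cfg.median_points)
    gyro = median3(np.asarray(gyro, dtype=float), cfg.median_points)
    n = accel.shape[0]
    filt = MadgwickIMU(beta=cfg.beta, fs=fs)
    if np.linalg.norm(accel[0]) > 0:
        filt.init_from_accel(accel[0])
    out = np.empty(n)
    for i in range(n):
        filt.update(gyro[i], accel[i])
        out[i] = filt.pitch_deg
    return out


def fuse_trace(imu: ImuTrace, cfg: FusionConfig | None = None,
               bias_compensate: bool = False):
    """Fuse all segments of an :class:`ImuTrace` into a MotionTrace.

    With ``bias_compensate`` the leading stationary window of each segment
    is used to estimate and remove per-axis offsets first.
    """
    from .traces import MotionTrace

    cfg = cfg or FusionConfig()
    angles = {}
    for seg in imu.segments:
        accel = imu.accel(seg).copy()
        gyro = imu.gyro(seg).copy()
        if bias_compensate:
            a_off, g_off = estimate_bias(accel, gyro, imu.fs,
                                         cfg.stationary_window)
            accel -= a_off
            gyro -= g_off
        angles[seg] = fuse_inclination(accel, gyro, imu.fs, cfg)
    return MotionTrace(
        fs=imu.fs,
        theta_shank=angles["shank"],
        theta_thigh=angles["thigh"],
        theta_hat=angles["hat"],
    )
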