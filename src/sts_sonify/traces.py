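"""Time-series containers for segment motion and inertial data.

Two containers travel through the pipeline:

* :class:`MotionTrace` — anteroposterior inclination of the three modeled
  body segments (shank, thigh, HAT = head-arms-trunk), in degrees.
  0 deg is vertical, positive is forward lean.
* :class:`ImuTrace` — per-segment 3-axis accelerometer (m/s^2) and
  gyroscope (deg/s) samples at a fixed rate.

Both round-trip through plain CSV with a unit-declaring comment header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Segment labels, ordered distal to proximal.
SEGMENTS = ("shank", "thigh", "hat")

#: Gravitational acceleration used throughout the package [m/s^2].
GRAVITY = 9.81

_IMU_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")


@dataclass
class MotionTrace:
    """Anteroposterior segment inclinations sampled at ``fs`` Hz."""

    fs: float
    theta_shank: np.ndarray
    theta_thigh: np.ndarray
    theta_hat: np.ndarray

    def __post_init__(self) -> None:
        self.theta_shank = np.asarray(self.theta_shank, dtype=float)
        self.theta_thigh = np.asarray(self.theta_thigh, dtype=float)
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = len(self.theta_shank)
        if len(self.theta_thigh) != n or len(self.theta_hat) != n:
            raise ValueError("segment angle series must have equal length")
        for name in ("theta_shank", "theta_thigh", "theta_hat"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(np.abs(arr) >= 180.0):
                raise ValueError(f"{name} exceeds +/-180 deg")

    def __len__(self) -> int:
        return len(self.theta_shank)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def angle(self, segment: str) -> np.ndarray:
        return getattr(self, f"theta_{segment}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "theta_shank": self.theta_shank,
                "theta_thigh": self.theta_thigh,
                "theta_hat": self.theta_hat,
            }
        )

    def to_csv(self, path) -> None:
        _write_commented_csv(
            path,
            self.to_frame(),
            f"# units: theta deg (0 = vertical, + = forward lean); fs = {self.fs:g} Hz",
        )

    @classmethod
    def from_csv(cls, path) -> "MotionTrace":
        df, fs = _read_commented_csv(path)
        return cls(
            fs=fs,
            theta_shank=df["theta_shank"].to_numpy(),
            theta_thigh=df["theta_thigh"].to_numpy(),
            theta_hat=df["theta_hat"].to_numpy(),
        )


@dataclass
class ImuTrace:
    """Per-segment accelerometer + gyroscope samples at ``fs`` Hz.

    ``data`` maps segment label -> (n, 6) array with columns
    ax, ay, az [m/s^2], gx, gy, gz [deg/s].  Sensor convention: x forward,
    z along the segment (up at 0 deg inclination), y the pitch axis; the
    pitch-axis gyro reads ``+d(theta)/dt`` for increasing forward lean and
    a stationary upright sensor reads (0, 0, +g) on the accelerometer.
    """

    fs: float
    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lengths = set()
        for seg, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 6:
                raise ValueError(f"segment {seg!r}: expected (n, 6) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"segment {seg!r} contains non-finite values")
            self.data[seg] = arr
            lengths.add(arr.shape[0])
        if len(lengths) > 1:
            raise ValueError("all segments must have equal length")

    def __len__(self) -> int:
        if not self.data:
            return 0
        return next(iter(self.data.values())).shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    @property
    def segments(self) -> tuple:
        return tuple(self.data)

    def accel(self, segment: str) -> np.ndarray:
        """(n, 3) accelerometer block [m/s^2]."""
        return self.data[segment][:, :3]

    def gyro(self, segment: str) -> np.ndarray:
        """(n, 3) gyroscope block [deg/s]."""
        return self.data[segment][:, 3:]

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for seg in self.data:
            for j, ch in enumerate(_IMU_CHANNELS):
                cols[f"{seg}_{ch}"] = self.data[seg][:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        _write_commented_csv(
            path,
            self.to_frame(),
            f"# units: accel m/s^2, gyro deg/s; fs = {self.fs:g} Hz",
        )

    @classmethod
    def from_csv(cls, path) -> "ImuTrace":
        df, fs = _read_commented_csv(path)
        segs = []
        for col in df.columns:
            if col.endswith("_ax"):
                segs.append(col[:-3])
        data = {}
        for seg in segs:
            data[seg] = np.column_stack(
                [df[f"{seg}_{ch}"].to_numpy() for ch in _IMU_CHANNELS]
            )
        return cls(fs=fs, data=data)


def _write_commented_csv(path, df: pd.DataFrame, header: str) -> None:
    buf = io.StringIO()
    buf.write(header + "\n")
    df.to_csv(buf, index=False, float_format="%.10g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_commented_csv(path):
    """Read a CSV written by :func:`_write_commented_csv`; recover fs."""
    with open(path) as fh:
        first = fh.readline()
    fs = None
    if first.startswith("#") and "fs =" in first:
        token = first.split("fs =")[1].split("Hz")[0]
        fs = float(token)
    df = pd.read_csv(path, comment="#")
    if fs is None:
        t = df["t"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
    return df, fs
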