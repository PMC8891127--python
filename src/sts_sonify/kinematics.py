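"""Sagittal 3-segment body reconstruction and CoM kinematics.

The body is modeled as three rigid segments — shank, thigh and HAT
(head-arms-trunk) — connected by frictionless pin joints (ankle, knee,
hip), in contact with the ground only at the distal shank.  Coordinates
are body-length units: the origin sits at the distal end of the shank
(ankle), y points up, x forward, and a unit distance equals total body
height with knees/hips extended.

Each segment CoM follows from its inclination and its distal joint::

    x_seg = x_joint + sin(theta) * L * D
    y_seg = y_joint + cos(theta) * L * D

with L the segment length as a fraction of body height and D the fraction
of segment length from the distal joint to the segment CoM.  The body CoM
is the segment-mass-weighted sum, with the three mass fractions
renormalized to 1 (feet and a separate arm segment are not modeled).

STS progression is summarized by the normalized distance from stand::

    d = |stand - CoM| / |stand - sit|

which is 1 at calibrated sitting, 0 at standing, and may exceed 1 when
the CoM moves beyond the sitting point (e.g. sit-back failures).  It is
deliberately not clipped here; clipping is the mapping layer's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import MotionTrace


@dataclass
class SegmentParams:
    """L: length / body height; D: distal-joint->CoM fraction of segment
    length; w: segment mass / body mass."""

    L: float
    D: float
    w: float

    def __post_init__(self) -> None:
        if not (0 < self.L < 1 and 0 < self.D < 1 and 0 < self.w < 1):
            raise ValueError("segment parameters must lie in (0, 1)")


def _default_shank() -> SegmentParams:
    return SegmentParams(L=0.246, D=0.567, w=0.093)


def _default_thigh() -> SegmentParams:
    return SegmentParams(L=0.245, D=0.567, w=0.200)


def _default_hat() -> SegmentParams:
    return SegmentParams(L=0.509, D=0.374, w=0.678)


@dataclass
class Anthropometry:
    """Normative segment parameters (editable per subject).

    Defaults follow the classic normative tables: segment lengths as
    fractions of stature (shank 0.246, thigh 0.245, HAT the remaining
    0.509 so the extended chain spans one body length), CoM locations
    measured from the distal joint (shank/thigh CoM at 0.433 of segment
    length from the proximal joint, HAT CoM at 0.374 of its length above
    the hip), and segment mass fractions (both shanks 0.093, both thighs
    0.200, HAT 0.678).  Mass fractions are renormalized over the three
    modeled segments when computing the body CoM.
    """

    shank: SegmentParams = field(default_factory=_default_shank)
    thigh: SegmentParams = field(default_factory=_default_thigh)
    hat: SegmentParams = field(default_factory=_default_hat)

    def __post_init__(self) -> None:
        total_L = self.shank.L + self.thigh.L + self.hat.L
        if total_L > 1.0 + 1e-9:
            raise ValueError("segment lengths exceed total body length")

    @property
    def weights(self) -> np.ndarray:
        """Mass fractions renormalized to sum to 1 over the 3 segments."""
        w = np.array([self.shank.w, self.thigh.w, self.hat.w])
        return w / w.sum()


@dataclass
class BodyState:
    """Joint and CoM coordinates (body-length units, ankle at origin).

    All fields are scalars or equal-length arrays, allowing a whole
    trajectory to be held in one instance.
    """

    knee: tuple
    hip: tuple
    seg_com: dict
    x_com: np.ndarray
    y_com: np.ndarray


def segment_com(theta_deg, distal_joint, L: float, D: float):
    """CoM of one segment from its inclination and distal joint position."""
    th = np.radians(theta_deg)
    x = distal_joint[0] + np.sin(th) * L * D
    y = distal_joint[1] + np.cos(th) * L * D
    return x, y


def chain_and_body_com(theta_shank, theta_thigh, theta_hat,
                       anthro: Anthropometry | None = None) -> BodyState:
    """Forward kinematics: joints bottom-up, then mass-weighted body CoM."""
    anthro = anthro or Anthropometry()
    ths = np.radians(np.asarray(theta_shank, dtype=float))
    tht = np.radians(np.asarray(theta_thigh, dtype=float))
    thh = np.asarray(theta_hat, dtype=float)

    ankle = (np.zeros_like(ths), np.zeros_like(ths))
    knee = (
        ankle[0] + np.sin(ths) * anthro.shank.L,
        ankle[1] + np.cos(ths) * anthro.shank.L,
    )
    hip = (
        knee[0] + np.sin(tht) * anthro.thigh.L,
        knee[1] + np.cos(tht) * anthro.thigh.L,
    )

    com_shank = segment_com(theta_shank, ankle, anthro.shank.L, anthro.shank.D)
    com_thigh = segment_com(theta_thigh, knee, anthro.thigh.L, anthro.thigh.D)
    com_hat = segment_com(thh, hip, anthro.hat.L, anthro.hat.D)

    w = anthro.weights
    x_com = w[0] * com_shank[0] + w[1] * com_thigh[0] + w[2] * com_hat[0]
    y_com = w[0] * com_shank[1] + w[1] * com_thigh[1] + w[2] * com_hat[1]

    return BodyState(
        knee=knee,
        hip=hip,
        seg_com={"shank": com_shank, "thigh": com_thigh, "hat": com_hat},
        x_com=x_com,
        y_com=y_com,
    )


def body_com_trajectory(trace: MotionTrace,
                        anthro: Anthropometry | None = None) -> BodyState:
    """Convenience: forward kinematics over a whole MotionTrace."""
    return chain_and_body_com(
        trace.theta_shank, trace.theta_thigh, trace.theta_hat, anthro
    )


@dataclass
class CalibrationPair:
    """Calibrated CoM coordinates at upright sitting and standing.

    The rectangle spanned by the two points is the "exercise space"
    within which STS progression is measured.
    """

    sit: tuple
    stand: tuple

    def __post_init__(self) -> None:
        self.sit = (float(self.sit[0]), float(self.sit[1]))
        self.stand = (float(self.stand[0]), float(self.stand[1]))
        if self.span == 0.0:
            raise ValueError("sit and stand calibration points coincide")
        # small slack: a calibrated standing CoM sits at x ~ 0 exactly,
        # so measurement noise may straddle the box edge
        eps = 0.02
        for x, y in (self.sit, self.stand):
            if not (-eps <= x <= 1.0 + eps and -eps <= y <= 1.0 + eps):
                raise ValueError("calibration points must lie in the unit box")

    @property
    def span(self) -> float:
        return float(np.hypot(self.stand[0] - self.sit[0],
                              self.stand[1] - self.sit[1]))


def distance_from_stand(x_com, y_com, cal: CalibrationPair):
    """Normalized Euclidean CoM distance from the stand point.

    1 at calibrated sitting, 0 at standing; may exceed 1 beyond sit.
    """
    num = np.hypot(cal.stand[0] - np.asarray(x_com),
                   cal.stand[1] - np.asarray(y_com))
    return num / cal.span


def calibrate(sit_trace: MotionTrace, stand_trace: MotionTrace,
              anthro: Anthropometry | None = None) -> CalibrationPair:
    """Time-averaged CoM over quiet sitting / standing windows."""
    states = [body_com_trajectory(tr, anthro) for tr in (sit_trace, stand_trace)]
    sit = (float(np.mean(states[0].x_com)), float(np.mean(states[0].y_com)))
    stand = (float(np.mean(states[1].x_com)), float(np.mean(states[1].y_com)))
    return CalibrationPair(sit=sit, stand=stand)


def calibration_from_postures(posture=None,
                              anthro: Anthropometry | None = None
                              ) -> CalibrationPair:
    """CalibrationPair directly from configured sit/stand posture angles."""
    from .simulate import PostureConfig

    posture = posture or PostureConfig()
    sit = chain_and_body_com(posture.sit_shank, posture.sit_thigh,
                             posture.sit_hat, anthro)
    stand = chain_and_body_com(posture.stand_shank, posture.stand_thigh,
                               posture.stand_hat, anthro)
    return CalibrationPair(
        sit=(float(sit.x_com), float(sit.y_com)),
        stand=(float(stand.x_com), float(stand.y_com)),
    )
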