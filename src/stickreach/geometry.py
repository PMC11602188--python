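"""Planar geometry of a rigid two-handed stick.

The apparatus is a virtual stick held at two points: the left hand grips the
far (left) end and the right hand grips the stick 15 cm to the right of it.
The controlled end-effector is the stick's right tip, 40 cm from the left hand
and 25 cm from the right hand. This module maps between the two equivalent
descriptions of the stick's configuration:

* a :class:`StickPose` — tip position plus stick-tilt angle, and
* a :class:`HandPair` — the two hand (handle) positions.

Angles are degrees at the API boundary, counter-clockwise positive, with 0°
meaning the stick lies along +x (tip to the right of the hands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StickGeometry",
    "StickPose",
    "HandPair",
    "hands_from_pose",
    "pose_from_hands",
    "hand_displacements",
]


@dataclass(frozen=True)
class StickGeometry:
    """Rigid-stick dimensions in cm.

    ``right_to_tip`` must equal ``left_to_tip - grip_separation``: the right
    hand sits between the left hand and the tip on the same rigid segment.
    """

    stick_length: float = 40.0
    grip_separation: float = 15.0
    left_to_tip: float = 40.0
    right_to_tip: float = 25.0

    def __post_init__(self) -> None:
        for name in ("stick_length", "grip_separation", "left_to_tip", "right_to_tip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.grip_separation >= self.left_to_tip:
            raise ValueError("grip_separation must be smaller than left_to_tip")
        if abs(self.right_to_tip - (self.left_to_tip - self.grip_separation)) > 1e-9:
            raise ValueError(
                "inconsistent geometry: right_to_tip must equal left_to_tip - grip_separation"
            )


def _normalize_angle_deg(angle: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (float(angle) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class StickPose:
    """Tip position (cm) and stick-tilt angle (deg, CCW positive, 0 = horizontal)."""

    tip: np.ndarray
    tilt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float).reshape(2))
        object.__setattr__(self, "tilt", _normalize_angle_deg(self.tilt))


@dataclass(frozen=True)
class HandPair:
    """Left and right hand positions in cm."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", np.asarray(self.left, dtype=float).reshape(2))
        object.__setattr__(self, "right", np.asarray(self.right, dtype=float).reshape(2))


def _stick_unit(tilt_deg: float) -> np.ndarray:
    """Unit vector pointing from the left end toward the tip."""
    t = np.deg2rad(tilt_deg)
    return np.array([np.cos(t), np.sin(t)])


def hands_from_pose(pose: StickPose, geom: StickGeometry = StickGeometry()) -> HandPair:
    """Hand positions implied by a stick pose.

    The left hand lies ``left_to_tip`` behind the tip along the stick axis and
    the right hand ``right_to_tip`` behind it, so the grip separation is
    preserved exactly.
    """
    u = _stick_unit(pose.tilt)
    return HandPair(left=pose.tip - geom.left_to_tip * u, right=pose.tip - geom.right_to_tip * u)


def pose_from_hands(
    hands: HandPair, geom: StickGeometry = StickGeometry(), tol: float = 1e-3
) -> StickPose:
    """Stick pose implied by the two hand positions.

    Raises ``ValueError`` if the hands violate the rigid grip separation by
    more than ``tol`` cm.
    """
    v = hands.right - hands.left
    sep = float(np.hypot(*v))
    if abs(sep - geom.grip_separation) > tol:
        raise ValueError(
            f"hand separation {sep:.6f} cm deviates from grip separation "
            f"{geom.grip_separation} cm by more than {tol} cm"
        )
    tilt = float(np.rad2deg(np.arctan2(v[1], v[0])))
    tip = hands.left + geom.left_to_tip * (v / sep)
    return StickPose(tip=tip, tilt=tilt)


def hand_displacements(
    start: StickPose, end: StickPose, geom: StickGeometry = StickGeometry()
) -> tuple[float, float]:
    """Euclidean distance travelled by each hand between two poses (cm)."""
    h0 = hands_from_pose(start, geom)
    h1 = hands_from_pose(end, geom)
    return (
        float(np.hypot(*(h1.left - h0.left))),
        float(np.hypot(*(h1.right - h0.right))),
    )
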