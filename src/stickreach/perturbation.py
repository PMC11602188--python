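"""Visual perturbations of the displayed stick.

Three regimes are used in the adaptation phase, all purely visual (the
physical stick is unchanged):

* **tip rotation** (end-effector relevant): the displayed tip position is
  rotated about the trial's start position, either gradually (1 deg per trial
  up to 30 deg by default) or abruptly (full 30 deg from trial 1). The
  displayed stick-tilt is unchanged.
* **tilt about the tip** (end-effector irrelevant): the displayed stick is
  rotated about the tip by an angle proportional to the tip's displacement
  from the start (0.6 deg/cm by default, i.e. 6 deg at the 10 cm target),
  CW or CCW. The displayed tip position is unchanged.
* their combination.

States on the tip-movement-direction / stick-tilt-angle (TMD, STA) planes are
tagged with the frame they live in (``physical`` — what the hands do;
``visual`` — what is displayed) and cross-frame arithmetic is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .geometry import StickPose

__all__ = [
    "PerturbationSpec",
    "PlaneState",
    "tip_rotation_at_trial",
    "tilt_perturbation_at_displacement",
    "apply_visual_map",
    "invert_visual_map",
    "plane_map",
]

_TIP_MODES = ("none", "gradual", "abrupt")


@dataclass(frozen=True)
class PlaneState:
    """A point on a (TMD, STA) plane, in degrees, tagged with its frame."""

    tmd: float
    sta: float
    frame: str = "physical"

    def __post_init__(self) -> None:
        if self.frame not in ("physical", "visual"):
            raise ValueError(f"frame must be 'physical' or 'visual', got {self.frame!r}")

    def require_frame(self, frame: str) -> "PlaneState":
        if self.frame != frame:
            raise ValueError(f"expected a {frame}-frame state, got {self.frame}-frame")
        return self


@dataclass(frozen=True)
class PerturbationSpec:
    """Schedule and gains of the visual perturbation.

    ``tip_mode``: 'none', 'gradual' (tip_step deg/trial up to tip_max) or
    'abrupt' (tip_max from the first adaptation trial). ``tilt_gain`` is the
    displacement-proportional tilt rotation in deg/cm, applied with sign
    ``tilt_sign`` (+1 CCW, -1 CW, 0 off).
    """

    tip_mode: str = "none"
    tip_max: float = 30.0
    tip_step: float = 1.0
    tilt_gain: float = 0.6
    tilt_sign: int = 0

    def __post_init__(self) -> None:
        if self.tip_mode not in _TIP_MODES:
            raise ValueError(f"tip_mode must be one of {_TIP_MODES}, got {self.tip_mode!r}")
        if self.tip_mode == "gradual" and self.tip_step <= 0:
            raise ValueError("tip_step must be > 0 in gradual mode")
        if self.tilt_gain < 0:
            raise ValueError("tilt_gain must be >= 0")
        if self.tilt_sign not in (-1, 0, 1):
            raise ValueError("tilt_sign must be -1, 0 or +1")

    def to_dict(self) -> dict:
        """Serialise with the config-file key names."""
        return {
            "tip_mode": self.tip_mode,
            "tip_max_deg": self.tip_max,
            "tip_step_deg": self.tip_step,
            "tilt_gain_deg_per_cm": self.tilt_gain,
            "tilt_sign": self.tilt_sign,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PerturbationSpec":
        return cls(
            tip_mode=d.get("tip_mode", "none"),
            tip_max=float(d.get("tip_max_deg", 30.0)),
            tip_step=float(d.get("tip_step_deg", 1.0)),
            tilt_gain=float(d.get("tilt_gain_deg_per_cm", 0.6)),
            tilt_sign=int(d.get("tilt_sign", 0)),
        )


def tip_rotation_at_trial(trial_index: int, spec: PerturbationSpec) -> float:
    """Tip-rotation magnitude (deg CCW) at a 1-based adaptation trial index."""
    if trial_index < 1:
        raise ValueError(f"trial_index must be >= 1, got {trial_index}")
    if spec.tip_mode == "none":
        return 0.0
    if spec.tip_mode == "abrupt":
        return spec.tip_max
    return min(trial_index * spec.tip_step, spec.tip_max)


def tilt_perturbation_at_displacement(r: float, spec: PerturbationSpec) -> float:
    """Visual tilt rotation (deg) when the tip is ``r`` cm from the start."""
    if r < 0:
        raise ValueError("displacement must be >= 0")
    return spec.tilt_sign * spec.tilt_gain * r


def _rot(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def apply_visual_map(
    phys: StickPose, start: np.ndarray, trial_index: int, spec: PerturbationSpec
) -> StickPose:
    """Displayed pose for a physical pose on a given adaptation trial."""
    start = np.asarray(start, dtype=float).reshape(2)
    rho = tip_rotation_at_trial(trial_index, spec)
    rel = phys.tip - start
    vis_tip = start + _rot(rho) @ rel
    r = float(np.hypot(*rel))
    vis_tilt = phys.tilt + tilt_perturbation_at_displacement(r, spec)
    return StickPose(tip=vis_tip, tilt=vis_tilt)


def invert_visual_map(
    vis: StickPose, start: np.ndarray, trial_index: int, spec: PerturbationSpec
) -> StickPose:
    """Physical pose that produced a displayed pose (exact inverse).

    The tip rotation is an isometry about the start, so the tip displacement
    radius — and with it the displacement-proportional tilt offset — is the
    same in both frames, making the map invertible in closed form.
    """
    start = np.asarray(start, dtype=float).reshape(2)
    rho = tip_rotation_at_trial(trial_index, spec)
    rel = vis.tip - start
    phys_tip = start + _rot(-rho) @ rel
    r = float(np.hypot(*rel))
    phys_tilt = vis.tilt - tilt_perturbation_at_displacement(r, spec)
    return StickPose(tip=phys_tip, tilt=phys_tilt)


def plane_map(
    phys: PlaneState,
    trial_index: int,
    spec: PerturbationSpec,
    displacement: float = 10.0,
) -> PlaneState:
    """Visual-plane state for a physical-plane state.

    ``displacement`` is the tip displacement (cm) at which the state is read
    out; end-of-movement read-outs use the target distance (default 10 cm,
    where the tilt perturbation reaches its full value), at-peak-velocity
    read-outs pass the displacement of the peak-velocity sample.
    """
    phys.require_frame("physical")
    rho = tip_rotation_at_trial(trial_index, spec)
    return PlaneState(
        tmd=phys.tmd + rho,
        sta=phys.sta + tilt_perturbation_at_displacement(displacement, spec),
        frame="visual",
    )
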