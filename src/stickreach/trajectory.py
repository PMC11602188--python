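"""Within-trial kinematics of the stick.

Trials are point-to-point reaches of the stick tip with a bell-shaped speed
profile. The minimum-jerk quintic is used as the canonical profile: along-path
displacement r(t) = d (10 tau^3 - 15 tau^4 + 6 tau^5) with tau = t/T, which
gives a unimodal speed peaking at tau = 1/2 with value 1.875 d / T. The
stick-tilt angle ramps in proportion to tip displacement, reaching the
intended final tilt when the tip reaches the target; hand trajectories follow
from the rigid-stick geometry at every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import StickGeometry
from .optimum import TargetSpec
from .perturbation import PlaneState

__all__ = [
    "TrialKinematics",
    "min_jerk_tip",
    "peak_speed_min_jerk",
    "ramped_tilt",
    "speed_feedback",
    "synthesize_trial",
]

SPEED_RANGE_MM_S = (300.0, 450.0)


@dataclass(frozen=True)
class TrialKinematics:
    """Uniformly sampled trial: time (s), tip/left/right (cm), tilt (deg)."""

    time: np.ndarray
    tip: np.ndarray
    left: np.ndarray
    right: np.ndarray
    tilt: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("tip", "left", "right"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2), got {arr.shape}")
        if self.tilt.shape != (n,):
            raise ValueError("tilt length must match time")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self, trial: int = 1) -> pd.DataFrame:
        """Long-format table: trial, t_s, effector, x_cm, y_cm, tilt_deg."""
        frames = []
        for name, arr in (("tip", self.tip), ("left", self.left), ("right", self.right)):
            frames.append(
                pd.DataFrame(
                    {
                        "trial": trial,
                        "t_s": self.time,
                        "effector": name,
                        "x_cm": arr[:, 0],
                        "y_cm": arr[:, 1],
                        "tilt_deg": self.tilt,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialKinematics":
        """Rebuild from the long-format table of a single trial."""
        parts = {}
        for name in ("tip", "left", "right"):
            sub = df[df["effector"] == name].sort_values("t_s")
            if sub.empty:
                raise ValueError(f"trial table missing effector {name!r}")
            parts[name] = sub
        tip = parts["tip"]
        return cls(
            time=tip["t_s"].to_numpy(float),
            tip=tip[["x_cm", "y_cm"]].to_numpy(float),
            left=parts["left"][["x_cm", "y_cm"]].to_numpy(float),
            right=parts["right"][["x_cm", "y_cm"]].to_numpy(float),
            tilt=tip["tilt_deg"].to_numpy(float),
        )


def min_jerk_tip(target: TargetSpec, duration: float = 0.5, dt: float = 0.001) -> np.ndarray:
    """Along-path tip displacement series (cm) of a minimum-jerk reach.

    Samples at t = 0, dt, ..., duration; r(0) = 0 and r(duration) = d.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / dt))
    tau = np.arange(n + 1) * dt / duration
    return target.distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def peak_speed_min_jerk(distance_cm: float, duration: float) -> float:
    """Peak tip speed (mm/s) of the quintic profile: 1.875 d / T."""
    return 1.875 * distance_cm * 10.0 / duration


def ramped_tilt(
    displacement: np.ndarray, final_tilt: float, target: TargetSpec
) -> np.ndarray:
    """Tilt series ramping linearly with displacement: final_tilt * r / d."""
    r = np.asarray(displacement, dtype=float)
    if np.any(np.diff(r) < -1e-9):
        raise ValueError("displacement series must be non-decreasing")
    return final_tilt * r / target.distance


def speed_feedback(peak_speed_mm_s: float) -> str:
    """Trial feedback label: 'slow' below, 'fast' above the 300-450 mm/s band."""
    if peak_speed_mm_s < 0:
        raise ValueError("peak speed must be >= 0")
    lo, hi = SPEED_RANGE_MM_S
    if peak_speed_mm_s < lo:
        return "slow"
    if peak_speed_mm_s > hi:
        return "fast"
    return "ok"


def synthesize_trial(
    intent: PlaneState,
    target: TargetSpec,
    geom: StickGeometry = StickGeometry(),
    duration: float = 0.5,
    dt: float = 0.001,
    start: np.ndarray = (0.0, 0.0),
    initial_tilt: float = 0.0,
    noise_sd_cm: float = 0.0,
    noise_seed: int | None = None,
) -> TrialKinematics:
    """Sampled trial realising a planned (TMD, STA) intent.

    The tip moves on a straight path along ``intent.tmd`` with a minimum-jerk
    displacement profile while the tilt ramps from ``initial_tilt`` to
    ``initial_tilt + intent.sta`` in proportion to displacement. With
    ``noise_sd_cm`` > 0, iid Gaussian jitter is added to the tip path (hands
    stay geometry-consistent with the noisy tip). Deterministic given
    ``noise_seed``.
    """
    intent.require_frame("physical")
    start = np.asarray(start, dtype=float).reshape(2)
    r = min_jerk_tip(target, duration, dt)
    direction = np.deg2rad(intent.tmd)
    u = np.array([np.cos(direction), np.sin(direction)])
    tip = start + np.outer(r, u)
    if noise_sd_cm > 0:
        rng = np.random.default_rng(noise_seed)
        tip = tip + rng.normal(0.0, noise_sd_cm, size=tip.shape)
    tilt = initial_tilt + ramped_tilt(r, intent.sta, target)
    n = len(r)
    left = np.empty((n, 2))
    right = np.empty((n, 2))
    t_rad = np.deg2rad(tilt)
    axis = np.column_stack([np.cos(t_rad), np.sin(t_rad)])
    left[:] = tip - geom.left_to_tip * axis
    right[:] = tip - geom.right_to_tip * axis
    return TrialKinematics(
        time=np.arange(n) * dt, tip=tip, left=left, right=right, tilt=tilt
    )
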