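"""Trial analysis: filtering, peak-velocity read-outs, segments, statistics.

Kinematic series are low-pass filtered (10 Hz, fourth-order Butterworth,
zero-phase) before speeds are computed. A trial's movement pattern is
summarised by two angles read out at the tip's peak velocity:

* TMD (tip-movement direction): angle of the chord from the trial's start
  position to the tip position at the peak-velocity sample, CCW from +x;
* STA (stick-tilt angle): stick tilt at that sample relative to the trial's
  initial tilt.

The chord definition coincides with the instantaneous velocity direction for
the straight paths generated here and is robust to noise; an instantaneous
read-out is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .trajectory import TrialKinematics, speed_feedback

__all__ = [
    "TrialMeasures",
    "SegmentScheme",
    "default_segments",
    "lowpass",
    "tip_speed",
    "peak_velocity_index",
    "tmd_sta_at",
    "instantaneous_tmd_at",
    "movement_offset_index",
    "measure_trial",
    "segment_means",
    "trial_variability",
    "paired_t",
    "pearson_r",
    "cohens_d",
]


@dataclass(frozen=True)
class TrialMeasures:
    """Per-trial summary used throughout the pipeline."""

    trial: int
    phase: str
    target_dir: float
    tmd_peak: float
    sta_peak: float
    sta_offset: float
    peak_speed: float
    speed_flag: str


@dataclass(frozen=True)
class SegmentScheme:
    """Ordered, inclusive (label, first_trial, last_trial) windows."""

    segments: tuple

    def __post_init__(self) -> None:
        last = 0
        for label, first, lastt in self.segments:
            if first <= last:
                raise ValueError(f"segment {label!r} overlaps the previous one")
            if lastt < first:
                raise ValueError(f"segment {label!r} has last < first")
            last = lastt


def default_segments() -> SegmentScheme:
    """Nine adaptation-phase segments covering trials 1-240.

    The published segmentation lists 26-30 and 30-120 with trial 30 in both;
    it is normalised here to 26-30 and 31-120 so means are well-defined.
    """
    bounds = [(1, 5), (6, 10), (11, 15), (16, 20), (21, 25), (26, 30), (31, 120), (121, 210), (211, 240)]
    return SegmentScheme(tuple((f"{a}-{b}", a, b) for a, b in bounds))


def lowpass(
    x: np.ndarray, fs: float, cutoff_hz: float = 10.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (DC gain 1), applied along axis 0."""
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * order:
        raise ValueError(f"series of length {len(x)} too short for order-{order} filtering")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def tip_speed(kin: TrialKinematics, cutoff_hz: float = 10.0) -> np.ndarray:
    """Filtered tip speed (cm/s) from finite-difference velocities."""
    fs = 1.0 / kin.dt
    pos = lowpass(kin.tip, fs, cutoff_hz)
    vel = np.gradient(pos, kin.dt, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


def peak_velocity_index(kin: TrialKinematics, cutoff_hz: float = 10.0) -> int:
    """Index of the global tip-speed maximum (first index on ties)."""
    return int(np.argmax(tip_speed(kin, cutoff_hz)))


def tmd_sta_at(
    kin: TrialKinematics, index: int, start: np.ndarray | None = None
) -> tuple[float, float]:
    """(TMD, STA) in degrees at a sample index.

    TMD is the chord angle from ``start`` (default: first tip sample) to the
    tip at ``index``; STA is the tilt change from the first sample. Raises
    ``ValueError`` if the tip has not moved from the start at ``index``.
    """
    start = kin.tip[0] if start is None else np.asarray(start, dtype=float).reshape(2)
    rel = kin.tip[index] - start
    if np.hypot(*rel) < 1e-12:
        raise ValueError("tip displacement is zero at the requested sample")
    tmd = float(np.rad2deg(np.arctan2(rel[1], rel[0])))
    sta = float(kin.tilt[index] - kin.tilt[0])
    return tmd, sta


def instantaneous_tmd_at(kin: TrialKinematics, index: int, cutoff_hz: float = 10.0) -> float:
    """Alternative TMD read-out: direction of the filtered tip velocity."""
    fs = 1.0 / kin.dt
    pos = lowpass(kin.tip, fs, cutoff_hz)
    vel = np.gradient(pos, kin.dt, axis=0)[index]
    if np.hypot(*vel) < 1e-12:
        raise ValueError("tip velocity is zero at the requested sample")
    return float(np.rad2deg(np.arctan2(vel[1], vel[0])))


def movement_offset_index(
    kin: TrialKinematics, target_distance: float, cutoff_hz: float = 10.0
) -> int:
    """Movement-offset sample: first index with displacement >= target distance
    and speed below 5% of the peak; falls back to the last sample."""
    speed = tip_speed(kin, cutoff_hz)
    disp = np.hypot(*(kin.tip - kin.tip[0]).T)
    ok = np.flatnonzero((disp >= target_distance - 1e-9) & (speed < 0.05 * speed.max()))
    return int(ok[0]) if ok.size else len(speed) - 1


def measure_trial(
    kin: TrialKinematics,
    trial: int,
    phase: str,
    target_dir: float,
    target_distance: float = 10.0,
    cutoff_hz: float = 10.0,
    start: np.ndarray | None = None,
) -> TrialMeasures:
    """Full per-trial read-out (peak-velocity TMD/STA, offset STA, speed flag)."""
    ipk = peak_velocity_index(kin, cutoff_hz)
    tmd, sta = tmd_sta_at(kin, ipk, start)
    ioff = movement_offset_index(kin, target_distance, cutoff_hz)
    sta_off = float(kin.tilt[ioff] - kin.tilt[0])
    peak_mm_s = float(tip_speed(kin, cutoff_hz)[ipk] * 10.0)
    return TrialMeasures(
        trial=trial,
        phase=phase,
        target_dir=target_dir,
        tmd_peak=tmd,
        sta_peak=sta,
        sta_offset=sta_off,
        peak_speed=peak_mm_s,
        speed_flag=speed_feedback(peak_mm_s),
    )


def segment_means(measures: pd.DataFrame, scheme: SegmentScheme | None = None) -> pd.DataFrame:
    """Per-segment mean TMD and STA over adaptation-phase trials.

    ``measures`` needs columns ``trial``, ``tmd_deg``, ``sta_deg`` (trial
    numbers 1-based within the adaptation phase). Raises on empty segments.
    """
    scheme = scheme or default_segments()
    rows = []
    for label, first, last in scheme.segments:
        sub = measures[(measures["trial"] >= first) & (measures["trial"] <= last)]
        if sub.empty:
            raise ValueError(f"segment {label!r} contains no trials")
        rows.append(
            {
                "segment": label,
                "first_trial": first,
                "last_trial": last,
                "n": len(sub),
                "tmd_deg": sub["tmd_deg"].mean(),
                "sta_deg": sub["sta_deg"].mean(),
            }
        )
    return pd.DataFrame(rows)


def trial_variability(
    measures: pd.DataFrame, first_trial: int = 121, last_trial: int = 240
) -> tuple[float, float]:
    """Sample SD of (TMD, STA) over a late-adaptation trial window."""
    sub = measures[(measures["trial"] >= first_trial) & (measures["trial"] <= last_trial)]
    if len(sub) < 2:
        raise ValueError("variability window must contain at least 2 trials")
    return float(sub["tmd_deg"].std(ddof=1)), float(sub["sta_deg"].std(ddof=1))


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Paired t statistic and degrees of freedom."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_pair(x, y)
    if np.std(x - y, ddof=1) == 0:
        raise ValueError("zero variance of differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def cohens_d(x: np.ndarray, y: np.ndarray | float = 0.0, paired: bool = True) -> float:
    """Effect size: mean difference / SD of differences (paired, or vs. a
    reference value); mean difference / pooled SD for two independent samples."""
    x = np.asarray(x, float)
    if paired or np.isscalar(y):
        diff = x - (y if np.isscalar(y) else np.asarray(y, float))
        sd = np.std(diff, ddof=1)
        if sd == 0:
            raise ValueError("zero variance of differences")
        return float(np.mean(diff) / sd)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((np.mean(x) - np.mean(y)) / pooled)


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("paired inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
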