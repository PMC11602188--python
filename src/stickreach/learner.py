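"""Trial-by-trial adaptation constrained to the baseline TMD-STA relation.

The synthetic participant plans a physical (TMD, STA) intent for each trial,
executes it with additive motor noise, observes the displayed (visual) state
through the perturbation map, and computes two visual prediction errors:

* a task error: target direction minus the visual TMD;
* a tilt error: the STA the baseline relation predicts for the seen TMD,
  minus the seen STA.

Both errors drive a correction, but the correction the body can express is
constrained to the baseline relation: the learning-rate-weighted error vector
(eta_m * e_tmd, eta_a * e_sta) is projected onto the unit tangent of the
relation at the current intent, so every update moves the intent along the
relation. Retention decays the intent toward the baseline point for the
current target. With the tilt-error rate eta_a > 0, end-effector-irrelevant
tilt perturbations therefore drag the task-relevant TMD with them, and a
residual TMD error persists at the steady state of tip-rotation adaptation.

An optional slope-normalised mode divides the tilt-error sensitivity by the
relation's slope magnitude, making shallow-relation participants correct tilt
errors more strongly; it is off by default (see docs/methods.md).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .perturbation import PerturbationSpec, PlaneState, plane_map, tip_rotation_at_trial
from .relation import BaselineRelation

__all__ = [
    "LearnerParams",
    "LearnerState",
    "prediction_errors",
    "update_state",
    "simulate_adaptation",
    "ParamFitResult",
    "fit_params",
]


@dataclass(frozen=True)
class LearnerParams:
    """Free parameters of the update rule.

    eta_tmd / eta_sta: learning rates on the task and tilt errors (0..1);
    retention_loss: per-trial decay toward the baseline intent (0..0.2);
    motor_noise_tmd / motor_noise_sta: execution-noise SDs in degrees.
    """

    eta_tmd: float = 0.1
    eta_sta: float = 0.1
    retention_loss: float = 0.0
    motor_noise_tmd: float = 1.0
    motor_noise_sta: float = 0.2
    seed: int = 0
    slope_normalized: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_tmd <= 1.0 and 0.0 <= self.eta_sta <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not (0.0 <= self.retention_loss <= 0.2):
            raise ValueError("retention_loss must lie in [0, 0.2]")
        if self.motor_noise_tmd < 0 or self.motor_noise_sta < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class LearnerState:
    """Planned physical (TMD, STA) intent for the next trial."""

    intent: PlaneState

    def __post_init__(self) -> None:
        self.intent.require_frame("physical")


def prediction_errors(
    visual: PlaneState, target_dir: float, relation: BaselineRelation
) -> tuple[float, float]:
    """Visual task error and tilt error (deg) for a displayed state."""
    visual.require_frame("visual")
    e_tmd = target_dir - visual.tmd
    e_sta = relation.evaluate(visual.tmd) - visual.sta
    return float(e_tmd), float(e_sta)


def update_state(
    state: LearnerState,
    errors: tuple[float, float],
    params: LearnerParams,
    relation: BaselineRelation,
    baseline_intent: PlaneState | None = None,
) -> LearnerState:
    """One constrained-correction update.

    The weighted error vector is projected onto the relation tangent at the
    current intent; retention decays the intent toward ``baseline_intent``
    (default: the origin-relation point (0, g(0))).
    """
    e_tmd, e_sta = errors
    intent = state.intent
    s = relation.slope(intent.tmd)
    tangent = np.array([1.0, s]) / np.sqrt(1.0 + s * s)
    eta_a = params.eta_sta
    if params.slope_normalized:
        eta_a = eta_a / max(abs(s), 1e-3)
    u = np.array([params.eta_tmd * e_tmd, eta_a * e_sta])
    step = float(u @ tangent) * tangent
    if baseline_intent is None:
        baseline_intent = PlaneState(tmd=0.0, sta=float(relation.evaluate(0.0)), frame="physical")
    lam = params.retention_loss
    new = np.array([intent.tmd, intent.sta])
    base = np.array([baseline_intent.tmd, baseline_intent.sta])
    new = base + (1.0 - lam) * (new - base) + step
    return LearnerState(intent=PlaneState(tmd=float(new[0]), sta=float(new[1]), frame="physical"))


def simulate_adaptation(
    n_trials: int,
    params: LearnerParams,
    relation: BaselineRelation,
    spec: PerturbationSpec,
    target_dir: float = 0.0,
    target_distance: float = 10.0,
    rng: np.random.Generator | None = None,
    initial_intent: PlaneState | None = None,
) -> pd.DataFrame:
    """Simulate the adaptation phase trial by trial.

    Per trial: execute the intent with motor noise, map it through the visual
    perturbation (end-of-movement read-out, displacement = target distance),
    compute the prediction errors, and update the intent. Returns a tidy
    table with one row per trial. Deterministic given ``rng``.
    """
    rng = rng or np.random.default_rng(params.seed)
    baseline = PlaneState(
        tmd=target_dir, sta=float(relation.evaluate(target_dir)), frame="physical"
    )
    state = LearnerState(intent=initial_intent or baseline)
    rows = []
    for trial in range(1, n_trials + 1):
        intent = state.intent
        noise = (
            rng.normal(0.0, params.motor_noise_tmd),
            rng.normal(0.0, params.motor_noise_sta),
        ) if (params.motor_noise_tmd > 0 or params.motor_noise_sta > 0) else (0.0, 0.0)
        executed = PlaneState(
            tmd=intent.tmd + noise[0], sta=intent.sta + noise[1], frame="physical"
        )
        visual = plane_map(executed, trial, spec, displacement=target_distance)
        e_tmd, e_sta = prediction_errors(visual, target_dir, relation)
        rows.append(
            {
                "trial": trial,
                "intent_tmd_deg": intent.tmd,
                "intent_sta_deg": intent.sta,
                "exec_tmd_deg": executed.tmd,
                "exec_sta_deg": executed.sta,
                "vis_tmd_deg": visual.tmd,
                "vis_sta_deg": visual.sta,
                "e_tmd_deg": e_tmd,
                "e_sta_deg": e_sta,
            }
        )
        state = update_state(state, (e_tmd, e_sta), params, relation, baseline_intent=baseline)
    return pd.DataFrame(rows)


def _predict_series(
    n: int,
    eta_tmd: float,
    eta_sta: float,
    lam: float,
    relation: BaselineRelation,
    spec: PerturbationSpec,
    target_dir: float,
    target_distance: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-trial (TMD, STA) series of the default update rule.

    Algebraically identical to ``simulate_adaptation`` with zero noise (the
    tangent projection reduces to proj = (eta_m e_m + s eta_a e_a)/(1+s^2),
    applied along (1, s)); kept as a plain array loop for grid-search speed.
    """
    g0 = float(relation.evaluate(target_dir))
    m, a = float(target_dir), g0
    tilt_off = spec.tilt_sign * spec.tilt_gain * target_distance
    out_m, out_a = np.empty(n), np.empty(n)
    kx, ky = relation.knots[:, 0], relation.knots[:, 1]
    seg = np.diff(ky) / np.diff(kx)
    linear = bool(np.all(np.abs(seg - seg[0]) < 1e-12))
    s_const, y0, x0 = float(seg[0]), float(ky[0]), float(kx[0])
    for trial in range(1, n + 1):
        out_m[trial - 1], out_a[trial - 1] = m, a
        rho = tip_rotation_at_trial(trial, spec)
        vis_m, vis_a = m + rho, a + tilt_off
        e_m = target_dir - vis_m
        if linear:
            e_a = y0 + s_const * (vis_m - x0) - vis_a
            s = s_const
        else:
            e_a = float(relation.evaluate(vis_m)) - vis_a
            s = relation.slope(m)
        proj = (eta_tmd * e_m + s * eta_sta * e_a) / (1.0 + s * s)
        m = target_dir + (1.0 - lam) * (m - target_dir) + proj
        a = g0 + (1.0 - lam) * (a - g0) + proj * s
    return out_m, out_a


@dataclass(frozen=True)
class ParamFitResult:
    """Grid-search fit: best parameters, its SSE, and a degeneracy flag."""

    params: LearnerParams
    sse: float
    flat_objective: bool


def fit_params(
    exec_tmd: np.ndarray,
    exec_sta: np.ndarray,
    spec: PerturbationSpec,
    relation: BaselineRelation,
    eta_tmd_grid: np.ndarray | None = None,
    eta_sta_grid: np.ndarray | None = None,
    retention_grid: np.ndarray | None = None,
    target_dir: float = 0.0,
) -> ParamFitResult:
    """Recover learner parameters from an observed per-trial state series.

    For every grid combination the model is run noise-free under the same
    perturbation schedule and the summed squared deviation between observed
    and predicted (TMD, STA) series is computed; the arg-min is returned. A
    flat objective (identical SSE everywhere) is reported, not hidden.
    """
    exec_tmd = np.asarray(exec_tmd, dtype=float)
    exec_sta = np.asarray(exec_sta, dtype=float)
    n = len(exec_tmd)
    if len(exec_sta) != n:
        raise ValueError("TMD and STA series must have equal length")
    eta_tmd_grid = np.round(np.arange(0.02, 0.301, 0.01), 10) if eta_tmd_grid is None else np.asarray(eta_tmd_grid)
    eta_sta_grid = np.array([0.0, 0.05, 0.1, 0.15, 0.2]) if eta_sta_grid is None else np.asarray(eta_sta_grid)
    retention_grid = np.array([0.0, 0.02, 0.05]) if retention_grid is None else np.asarray(retention_grid)
    best = None
    sses = []
    for em, ea, lam in itertools.product(eta_tmd_grid, eta_sta_grid, retention_grid):
        pred_m, pred_a = _predict_series(n, float(em), float(ea), float(lam), relation, spec, target_dir)
        sse = float(np.sum((pred_m - exec_tmd) ** 2) + np.sum((pred_a - exec_sta) ** 2))
        sses.append(sse)
        if best is None or sse < best[0]:
            p = LearnerParams(
                eta_tmd=float(em), eta_sta=float(ea), retention_loss=float(lam),
                motor_noise_tmd=0.0, motor_noise_sta=0.0,
            )
            best = (sse, p)
    flat = bool(np.ptp(sses) < 1e-12)
    return ParamFitResult(params=best[1], sse=best[0], flat_objective=flat)
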