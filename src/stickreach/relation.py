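"""The baseline TMD-STA relationship.

During unperturbed reaching, the stick-tilt angle (STA) observed at the tip's
peak velocity is a monotone increasing function g of the tip-movement
direction (TMD): reaching CCW targets is accompanied by CCW stick tilt. The
relationship is represented as a monotone piecewise-linear interpolant over
per-target knots, with linear extrapolation beyond the outermost knots. Its
local slope g'(m) is what constrains trial-by-trial corrections in the
adaptation model.

Fitting is exposed both as a scikit-learn style estimator
(:class:`BaselineRelationEstimator`) and as the functional wrapper
:func:`fit_relation`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.isotonic import IsotonicRegression
from sklearn.utils.validation import check_is_fitted

from .geometry import StickGeometry
from .optimum import PROTOCOL_DIRECTIONS, predicted_relation
from .perturbation import PlaneState

__all__ = [
    "BaselineRelation",
    "BaselineRelationEstimator",
    "fit_relation",
    "linear_relation",
    "relation_from_optimum",
]


@dataclass(frozen=True)
class BaselineRelation:
    """Monotone piecewise-linear mapping g: TMD (deg) -> STA (deg)."""

    knots: np.ndarray  # shape (k, 2): columns tmd, sta

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float).reshape(-1, 2)
        if len(k) < 2:
            raise ValueError("a relation needs at least 2 knots")
        if np.any(np.diff(k[:, 0]) <= 0):
            raise ValueError("knot TMD values must be strictly increasing")
        if np.any(np.diff(k[:, 1]) < -1e-12):
            raise ValueError("knot STA values must be non-decreasing (monotone relation)")
        object.__setattr__(self, "knots", k)

    def evaluate(self, tmd: float | np.ndarray) -> float | np.ndarray:
        """g(tmd): interpolate between knots, extrapolate with the end slopes."""
        x, y = self.knots[:, 0], self.knots[:, 1]
        m = np.asarray(tmd, dtype=float)
        out = np.interp(m, x, y)
        lo_slope = (y[1] - y[0]) / (x[1] - x[0])
        hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out = np.where(m < x[0], y[0] + lo_slope * (m - x[0]), out)
        out = np.where(m > x[-1], y[-1] + hi_slope * (m - x[-1]), out)
        return float(out) if np.isscalar(tmd) else out

    def slope(self, tmd: float) -> float:
        """g'(tmd): active-segment slope; mean of adjacent slopes at a knot."""
        x, y = self.knots[:, 0], self.knots[:, 1]
        seg = np.diff(y) / np.diff(x)
        m = float(tmd)
        if m <= x[0]:
            return float(seg[0]) if m < x[0] else float(seg[0])
        if m >= x[-1]:
            return float(seg[-1])
        hit = np.flatnonzero(np.isclose(m, x[1:-1], rtol=0.0, atol=1e-12))
        if hit.size:
            i = hit[0]
            return float(0.5 * (seg[i] + seg[i + 1]))
        i = int(np.searchsorted(x, m) - 1)
        return float(seg[i])

    def to_json(self) -> str:
        return json.dumps({"knots": self.knots.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "BaselineRelation":
        return cls(knots=np.asarray(json.loads(s)["knots"], dtype=float))


class BaselineRelationEstimator(RegressorMixin, BaseEstimator):
    """Fit the monotone TMD->STA relation from baseline trial read-outs.

    Observations are binned by nominal target direction (the nearest of
    ``bin_centers``); knots are per-bin means of (TMD, STA), with adjacent
    bins violating monotonicity pooled by isotonic regression (weighted by
    bin counts).

    Parameters
    ----------
    bin_centers : sequence of float, optional
        Nominal target directions in degrees; defaults to the nine-target
        protocol (0, +-10, +-20, +-30, +-40).

    Attributes
    ----------
    relation_ : BaselineRelation
        The fitted monotone piecewise-linear relation.
    """

    def __init__(self, bin_centers: Sequence[float] | None = None):
        self.bin_centers = bin_centers

    def fit(self, X, y):
        tmd = np.asarray(X, dtype=float).reshape(-1)
        sta = np.asarray(y, dtype=float).reshape(-1)
        if tmd.shape != sta.shape:
            raise ValueError("X and y must have the same length")
        centers = np.asarray(
            PROTOCOL_DIRECTIONS if self.bin_centers is None else sorted(self.bin_centers),
            dtype=float,
        )
        labels = np.argmin(np.abs(tmd[:, None] - centers[None, :]), axis=1)
        used = np.unique(labels)
        if used.size < 2:
            raise ValueError("baseline states must cover at least 2 distinct target bins")
        kx = np.array([tmd[labels == i].mean() for i in used])
        ky = np.array([sta[labels == i].mean() for i in used])
        kw = np.array([(labels == i).sum() for i in used], dtype=float)
        order = np.argsort(kx)
        kx, ky, kw = kx[order], ky[order], kw[order]
        iso = IsotonicRegression(increasing=True)
        ky = iso.fit_transform(kx, ky, sample_weight=kw)
        self.relation_ = BaselineRelation(knots=np.column_stack([kx, ky]))
        return self

    def predict(self, X):
        check_is_fitted(self, "relation_")
        return np.asarray(self.relation_.evaluate(np.asarray(X, dtype=float).reshape(-1)))


def fit_relation(
    baseline_states: Iterable[PlaneState],
    bin_centers: Sequence[float] | None = None,
) -> BaselineRelation:
    """Fit the relation from physical-frame plane states (peak-velocity read-outs)."""
    states = [s.require_frame("physical") for s in baseline_states]
    tmd = np.array([s.tmd for s in states])
    sta = np.array([s.sta for s in states])
    est = BaselineRelationEstimator(bin_centers=bin_centers).fit(tmd, sta)
    return est.relation_


def linear_relation(
    slope: float, directions: Sequence[float] = PROTOCOL_DIRECTIONS
) -> BaselineRelation:
    """Relation with constant slope through the origin, knotted at ``directions``."""
    d = np.asarray(sorted(directions), dtype=float)
    return BaselineRelation(knots=np.column_stack([d, slope * d]))


def relation_from_optimum(
    geom: StickGeometry = StickGeometry(),
    directions: Sequence[float] = PROTOCOL_DIRECTIONS,
    distance: float = 10.0,
) -> BaselineRelation:
    """Relation predicted by the minimum-hand-path-cost model."""
    pairs = predicted_relation(sorted(directions), geom, distance)
    return BaselineRelation(knots=np.asarray(pairs, dtype=float))
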