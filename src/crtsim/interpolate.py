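"""Required number of clusters from a Monte-Carlo power curve.

A power curve is a set of (cluster count, estimated power) points for one
design scenario and one cluster-size-variability level. The cluster count
achieving the target power (default 0.8) is found by solving the two-point
linear system through the bracketing points (C_lo, P_lo), (C_hi, P_hi):

    P = a * C + b,   C_hat = (target - b) / a

scanning left to right for the FIRST adjacent pair with P_lo < target and
P_hi >= target. Raw points are interpolated directly — no smoothing or
isotonic fitting — matching how simulation power curves are read in
practice. Curves that never cross the target yield an explicit
out-of-range result instead of an extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .power import PowerEstimate

logger = logging.getLogger(__name__)

__all__ = ["PowerCurve", "RequiredClusters", "interpolate_required", "percent_change"]


@dataclass(frozen=True)
class PowerCurve:
    """Ordered (cluster count, power estimate) points for one scenario/cv level."""

    points: tuple[tuple[int, PowerEstimate], ...]

    def __post_init__(self) -> None:
        cs = [c for c, _ in self.points]
        if len(cs) < 2:
            raise ValueError("a power curve needs at least two points")
        if any(b <= a for a, b in zip(cs, cs[1:])) :
            raise ValueError("cluster counts must be strictly increasing")

    @classmethod
    def from_estimates(cls, estimates: Sequence[PowerEstimate]) -> "PowerCurve":
        pts = sorted(((e.c_actual, e) for e in estimates), key=lambda t: t[0])
        return cls(tuple(pts))

    @property
    def c_values(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def powers(self) -> np.ndarray:
        return np.array([e.power for _, e in self.points])


@dataclass(frozen=True)
class RequiredClusters:
    """Interpolated cluster count reaching the target power.

    ``status`` is "ok" when a crossing exists; "all_above" when the curve
    starts at or above the target (the design is already overpowered at the
    smallest cluster count tried); "all_below" when it never reaches the
    target. In the non-ok cases ``c_hat`` is NaN.
    """

    c_hat: float
    target: float
    status: str
    bracket_low: tuple[float, float] | None  # (C, power) just below target
    bracket_high: tuple[float, float] | None  # (C, power) at/above target
    slope: float
    intercept: float

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def interpolate_required(curve: PowerCurve, target: float = 0.8) -> RequiredClusters:
    """Solve for the cluster count where the power curve crosses ``target``.

    Uses the first upward crossing scanning left to right; logs a warning
    when the curve is non-monotone by more than twice the Monte-Carlo
    standard error (noise larger than sampling error suggests too few
    replicates).
    """
    cs = curve.c_values.astype(float)
    ps = curve.powers
    _warn_if_nonmonotone(curve)
    if ps[0] >= target:
        return RequiredClusters(float("nan"), target, "all_above", None, None,
                                float("nan"), float("nan"))
    for i in range(len(ps) - 1):
        if ps[i] < target <= ps[i + 1]:
            c_lo, p_lo = cs[i], ps[i]
            c_hi, p_hi = cs[i + 1], ps[i + 1]
            slope = (p_hi - p_lo) / (c_hi - c_lo)
            intercept = p_lo - slope * c_lo
            c_hat = (target - intercept) / slope
            return RequiredClusters(
                c_hat=float(c_hat),
                target=target,
                status="ok",
                bracket_low=(float(c_lo), float(p_lo)),
                bracket_high=(float(c_hi), float(p_hi)),
                slope=float(slope),
                intercept=float(intercept),
            )
    return RequiredClusters(float("nan"), target, "all_below", None, None,
                            float("nan"), float("nan"))


def _warn_if_nonmonotone(curve: PowerCurve) -> None:
    for (c1, e1), (c2, e2) in zip(curve.points, curve.points[1:]):
        drop = e1.power - e2.power
        tol = 2.0 * (e1.mc_se + e2.mc_se)
        if drop > tol:
            logger.warning(
                "power curve non-monotone beyond Monte-Carlo noise: "
                "P(%d)=%.4f > P(%d)=%.4f", c1, e1.power, c2, e2.power
            )


def percent_change(c_hat_cv: float, c80: float) -> float:
    """Percent inflation of the required cluster count relative to ``c80``."""
    if c80 <= 0:
        raise ValueError("c80 must be positive")
    return 100.0 * (c_hat_cv - c80) / c80
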