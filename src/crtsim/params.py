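"""Design parameters for an equal-armed, continuous-outcome CRT.

A :class:`ParameterSet` bundles the quantities a trial designer fixes up
front (type I/II error, mean cluster size, ICC, between-cluster variance,
and the cluster count ``c80`` that nominally gives 80% power at fixed
sizes) together with the two quantities derived from them: the residual
variance sigma_eps^2 and the calibrated effect size Delta.

The calibration is Murray's cluster-level formula: with t-quantiles on
``c80 - 2`` degrees of freedom,

    Delta^2 = 4 (sigma_eps^2 + mu * bcv) (t_{alpha/2} + t_beta)^2 / (mu * c80)

so that a two-arm trial with ``c80`` clusters of exactly ``mu`` members
has nominal power ``1 - beta`` for a two-sided level-``alpha`` test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = ["ParameterSet", "derive_residual_variance", "calibrate_effect_size"]


def derive_residual_variance(icc: float, bcv: float) -> float:
    """Residual (within-cluster) variance implied by an ICC and a BCV.

    The intraclass correlation is ICC = bcv / (bcv + sigma_eps^2); solving
    for the residual variance gives ``bcv * (1 - icc) / icc``.

    Parameters
    ----------
    icc : float
        Intraclass correlation coefficient, in (0, 1).
    bcv : float
        Between-cluster variance sigma_eta^2, > 0.
    """
    if not 0.0 < icc < 1.0:
        raise ValueError(f"icc must be in (0, 1), got {icc}")
    if bcv <= 0.0:
        raise ValueError(f"bcv must be positive, got {bcv}")
    return bcv * (1.0 - icc) / icc


@dataclass(frozen=True)
class ParameterSet:
    """One fully calibrated CRT design scenario.

    ``sigma_eps_sq`` and ``delta`` are derived in ``__post_init__``; callers
    supply only the free design parameters.
    """

    alpha: float
    mu: float
    icc: float
    bcv: float
    c80: int
    beta: float = 0.2
    sigma_eps_sq: float = field(init=False)
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if self.mu <= 3:
            raise ValueError(f"mean cluster size must exceed the minimum size 3, got {self.mu}")
        object.__setattr__(self, "sigma_eps_sq", derive_residual_variance(self.icc, self.bcv))
        object.__setattr__(self, "delta", calibrate_effect_size(self))

    @property
    def total_variance(self) -> float:
        return self.bcv + self.sigma_eps_sq


def calibrate_effect_size(params: ParameterSet) -> float:
    """Effect size Delta giving nominal 80% power at ``c80`` fixed-size clusters.

    Uses t-quantiles on ``c80 - 2`` degrees of freedom (the cluster-level
    degrees of freedom of the two-sample comparison of cluster means) and a
    two-sided test at level ``alpha``.
    """
    df = params.c80 - 2
    if df <= 0:
        raise ValueError(
            f"c80={params.c80} leaves non-positive degrees of freedom for the t-quantiles"
        )
    t_sum = stats.t.ppf(1.0 - params.alpha / 2.0, df) + stats.t.ppf(1.0 - params.beta, df)
    delta_sq = 4.0 * (params.sigma_eps_sq + params.mu * params.bcv) * t_sum**2 / (
        params.mu * params.c80
    )
    return math.sqrt(delta_sq)
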