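"""Monte-Carlo power estimation for one (parameter set, cluster count) pair.

Fixed-size power averages rejection indicators over independent trials in
which every cluster has exactly ``mu`` members. Variable-size power draws a
fresh negative-binomial cluster-size set for every replicate, simulates one
trial on it, and averages the rejection indicators — so cluster-size
variability and outcome variability are averaged jointly, one trial per
size set.

Replicates use deterministic per-replicate substreams spawned from the
caller's seed, so results are independent of batching or worker count and
any single replicate can be replayed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .inference import test_treatment_effect
from .params import ParameterSet
from .simulate import assign_arms, simulate_trial
from .sizes import draw_cluster_sizes, fixed_cluster_sizes

__all__ = ["PowerEstimate", "estimate_power_fixed", "estimate_power_variable"]


@dataclass(frozen=True)
class PowerEstimate:
    """Estimated rejection probability with its binomial Monte-Carlo error."""

    power: float
    n_sims: int
    c_actual: int
    cv_label: float
    n_rejections: int
    n_fallback: int  # replicates decided by the fallback test

    @property
    def mc_se(self) -> float:
        return sqrt(self.power * (1.0 - self.power) / self.n_sims)


def _replicate_rngs(seed_seq: np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in seed_seq.spawn(n)]


def _run_replicates(
    params: ParameterSet,
    c_actual: int,
    cv: float,
    n_sims: int,
    seed_seq: np.random.SeedSequence,
    method: str,
    delta_override: float | None = None,
) -> PowerEstimate:
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if c_actual < 4:
        raise ValueError(f"need c_actual >= 4 for a testable design, got {c_actual}")
    if delta_override is not None:
        params = _copy_with_delta(params, delta_override)
    rejections = 0
    fallbacks = 0
    for rng in _replicate_rngs(seed_seq, n_sims):
        if cv == 0.0:
            sizes = fixed_cluster_sizes(params.mu, c_actual)
        else:
            sizes = draw_cluster_sizes(params.mu, cv, c_actual, rng)
        arms = assign_arms(c_actual, rng)
        trial = simulate_trial(params, sizes, arms, rng)
        result = test_treatment_effect(trial, params.alpha, method=method)
        rejections += int(result.reject)
        fallbacks += int(not result.converged)
    return PowerEstimate(
        power=rejections / n_sims,
        n_sims=n_sims,
        c_actual=c_actual,
        cv_label=cv,
        n_rejections=rejections,
        n_fallback=fallbacks,
    )


def _copy_with_delta(params: ParameterSet, delta: float) -> ParameterSet:
    import copy

    out = copy.copy(params)
    object.__setattr__(out, "delta", delta)
    return out


def estimate_power_fixed(
    params: ParameterSet,
    c_actual: int,
    n_sims: int,
    rng: np.random.SeedSequence | int,
    method: str = "mixed",
    delta_override: float | None = None,
) -> PowerEstimate:
    """Power with all cluster sizes fixed at ``mu``.

    ``delta_override`` substitutes the calibrated effect size (e.g. 0 for a
    type-I-error check) without recalibrating the parameter set.
    """
    seed_seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    return _run_replicates(params, c_actual, 0.0, n_sims, seed_seq, method, delta_override)


def estimate_power_variable(
    params: ParameterSet,
    c_actual: int,
    cv: float,
    n_sets: int,
    rng: np.random.SeedSequence | int,
    method: str = "mixed",
    delta_override: float | None = None,
) -> PowerEstimate:
    """Power when cluster sizes are drawn at coefficient of variation ``cv``.

    One size set and one simulated trial per replicate; the mean rejection
    indicator over the ``n_sets`` replicates is the power estimate. ``cv=0``
    degenerates to the fixed-size design.
    """
    seed_seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    return _run_replicates(params, c_actual, cv, n_sets, seed_seq, method, delta_override)
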