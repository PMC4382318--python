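"""Two-level normal outcome generator for one simulated CRT.

Individual outcomes follow

    Y_jk = eta_k + Delta * X_k + eps_jk,
    eta_k ~ N(0, bcv),  eps_jk ~ N(0, sigma_eps^2)

with a shared random intercept eta_k per cluster and a binary per-cluster
treatment indicator X_k. Cluster intercepts are drawn before individual
errors, in cluster order, so a trial replays byte-identically from its
seed regardless of how the caller batches work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np

from .params import ParameterSet
from .sizes import ClusterSizeSet

__all__ = ["TrialData", "assign_arms", "simulate_trial", "write_trial"]


@dataclass(frozen=True)
class TrialData:
    """Individual-level outcomes with cluster membership and arm assignment."""

    outcomes: np.ndarray  # float, one entry per individual
    cluster_id: np.ndarray  # int, 0-based cluster index per individual
    arm: np.ndarray  # int {0,1}, one entry per *cluster*

    @property
    def n_clusters(self) -> int:
        return int(self.arm.size)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_id, minlength=self.n_clusters)


def assign_arms(n_clusters: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly split clusters half/half between control (0) and treatment (1).

    For odd ``n_clusters`` the arm receiving the extra cluster is itself
    chosen uniformly at random; the assignment order is a uniform
    permutation.
    """
    if n_clusters < 2:
        raise ValueError(f"need at least 2 clusters to form two arms, got {n_clusters}")
    n_treat = n_clusters // 2
    if n_clusters % 2 == 1 and rng.random() < 0.5:
        n_treat += 1
    arms = np.zeros(n_clusters, dtype=np.int64)
    arms[:n_treat] = 1
    rng.shuffle(arms)
    return arms


def simulate_trial(
    params: ParameterSet,
    sizes: ClusterSizeSet,
    assignment: np.ndarray,
    rng: np.random.Generator,
) -> TrialData:
    """Generate one trial's individual-level outcomes from the two-level model."""
    sz = sizes.sizes
    if sz.size != assignment.size:
        raise ValueError("sizes and assignment must have equal length")
    eta = rng.normal(0.0, np.sqrt(params.bcv), size=sz.size)
    n_total = int(sz.sum())
    eps = rng.normal(0.0, np.sqrt(params.sigma_eps_sq), size=n_total)
    cluster_id = np.repeat(np.arange(sz.size), sz)
    cluster_effect = eta + params.delta * assignment
    outcomes = cluster_effect[cluster_id] + eps
    return TrialData(outcomes=outcomes, cluster_id=cluster_id, arm=np.asarray(assignment))


def write_trial(trial: TrialData, fh: IO[str]) -> None:
    """Dump one trial as tidy text (cluster, arm, outcome) for debugging."""
    fh.write("cluster\tarm\toutcome\n")
    for cid, y in zip(trial.cluster_id, trial.outcomes):
        fh.write(f"{cid}\t{trial.arm[cid]}\t{y:.10g}\n")
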