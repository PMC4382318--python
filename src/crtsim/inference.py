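"""Per-trial hypothesis tests of the treatment effect.

Two methods are provided:

``mixed``
    A linear mixed model with a fixed treatment effect and a random
    cluster intercept, fit by REML and tested with a Wald t-statistic on
    ``n_clusters - 2`` degrees of freedom. Because both covariates
    (intercept and arm) are constant within cluster, the model collapses
    onto per-cluster sufficient statistics (size, mean, within-cluster
    sum of squares) and REML reduces to a one-dimensional profile over
    the variance ratio lambda = sigma_eta^2 / sigma_eps^2. This is exactly
    the random-intercept REML solution, just computed without building the
    individual-level design matrix.

``cluster-means``
    The two-sample pooled-variance t-test on unweighted per-cluster means
    (df = n_clusters - 2). For balanced designs this is the exact
    cluster-level analysis and agrees with the mixed model; under unequal
    sizes it is a valid but slightly less efficient test.

On a mixed-model fit failure the cluster-means test is used as fallback
and the result is flagged ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .simulate import TrialData

__all__ = ["TestResult", "test_treatment_effect", "cluster_summaries"]

METHODS = ("mixed", "cluster-means")


@dataclass(frozen=True)
class TestResult:
    estimate: float
    p_value: float
    reject: bool
    method_tag: str
    converged: bool


def cluster_summaries(trial: TrialData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster (size, mean, within-cluster sum of squares)."""
    k = trial.n_clusters
    sizes = np.bincount(trial.cluster_id, minlength=k).astype(np.float64)
    sums = np.bincount(trial.cluster_id, weights=trial.outcomes, minlength=k)
    means = sums / sizes
    sq = np.bincount(trial.cluster_id, weights=trial.outcomes**2, minlength=k)
    ssw = sq - sizes * means**2
    return sizes, means, np.maximum(ssw, 0.0)


def _reml_profile(
    lam: float,
    sizes: np.ndarray,
    means: np.ndarray,
    x: np.ndarray,
    ssw_total: float,
    n_total: float,
):
    """Profiled -2 REML criterion and the WLS pieces at a given variance ratio."""
    w = sizes / (1.0 + lam * sizes)
    xtw = x.T * w
    xtwx = xtw @ x
    beta = np.linalg.solve(xtwx, xtw @ means)
    resid = means - x @ beta
    q = ssw_total + float(w @ resid**2)
    sign, logdet = np.linalg.slogdet(xtwx)
    crit = (n_total - 2.0) * np.log(q) + float(np.sum(np.log1p(lam * sizes))) + logdet
    return crit, beta, xtwx, q


def _mixed_model_test(trial: TrialData, alpha: float) -> TestResult:
    sizes, means, ssw = cluster_summaries(trial)
    k = trial.n_clusters
    n_total = float(sizes.sum())
    ssw_total = float(ssw.sum())
    x = np.column_stack([np.ones(k), trial.arm.astype(np.float64)])

    def objective(u: float) -> float:
        return _reml_profile(np.exp(u), sizes, means, x, ssw_total, n_total)[0]

    res = optimize.minimize_scalar(objective, bounds=(-30.0, 12.0), method="bounded")
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError("REML profile optimization failed")
    lam_hat = float(np.exp(res.x))
    # boundary check: a zero variance ratio may beat the interior optimum
    crit0 = _reml_profile(0.0, sizes, means, x, ssw_total, n_total)[0]
    if crit0 < res.fun:
        lam_hat = 0.0
    _, beta, xtwx, q = _reml_profile(lam_hat, sizes, means, x, ssw_total, n_total)
    sigma2 = q / (n_total - 2.0)
    cov = sigma2 * np.linalg.inv(xtwx)
    se = np.sqrt(cov[1, 1])
    tstat = beta[1] / se
    df = k - 2
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return TestResult(
        estimate=float(beta[1]),
        p_value=float(p),
        reject=bool(p < alpha),
        method_tag="mixed",
        converged=True,
    )


def _cluster_means_test(trial: TrialData, alpha: float, converged: bool = True) -> TestResult:
    _, means, _ = cluster_summaries(trial)
    treat = means[trial.arm == 1]
    ctrl = means[trial.arm == 0]
    res = stats.ttest_ind(treat, ctrl, equal_var=True)
    return TestResult(
        estimate=float(treat.mean() - ctrl.mean()),
        p_value=float(res.pvalue),
        reject=bool(res.pvalue < alpha),
        method_tag="cluster-means",
        converged=converged,
    )


def test_treatment_effect(
    trial: TrialData, alpha: float, method: str = "mixed"
) -> TestResult:
    """Two-sided test of the treatment coefficient at level ``alpha``.

    ``reject`` is True exactly when ``p_value < alpha``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    counts = np.bincount(trial.arm, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"degenerate design: need >= 2 clusters per arm, got {counts.tolist()}"
        )
    if method == "cluster-means":
        return _cluster_means_test(trial, alpha)
    try:
        return _mixed_model_test(trial, alpha)
    except (RuntimeError, np.linalg.LinAlgError):
        return _cluster_means_test(trial, alpha, converged=False)
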