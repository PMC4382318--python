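"""Calibrate the effect size a cluster-randomized trial is powered for.

Given the designer's inputs — type I/II error, mean cluster size, ICC,
between-cluster variance and the cluster count C80 that should give 80%
power at fixed sizes — the package derives the residual variance and the
minimum detectable (non-standardized) effect size Delta.
"""

from crtsim import ParameterSet

params = ParameterSet(alpha=0.05, mu=75, icc=0.006, bcv=0.1, c80=60)

print(f"residual variance sigma_eps^2 = {params.sigma_eps_sq:.4f}")
print(f"total outcome variance        = {params.total_variance:.4f}")
print(f"calibrated effect size Delta  = {params.delta:.3f}")
print()
print("Delta is the smallest mean difference between arms that a trial with")
print(f"{params.c80} clusters of exactly {params.mu:g} participants detects with 80% power")
print(f"at two-sided alpha = {params.alpha}.")
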