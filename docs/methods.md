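# Methods

`crtsim` estimates the statistical power of equal-armed, parallel-group
cluster-randomized trials (CRTs) with a continuous outcome, by direct
Monte-Carlo simulation, and quantifies how much the number of clusters
needed for 80% power inflates when cluster sizes vary.

## Data-generating model

Individual outcomes follow a two-level normal model

    Y_jk = eta_k + Delta * X_k + eps_jk,
    eta_k ~ N(0, sigma_eta^2),   eps_jk ~ N(0, sigma_eps^2),

where `k` indexes clusters, `j` individuals within cluster, `X_k` is the
binary arm indicator (constant within cluster) and `Delta` is the
non-standardized treatment effect. The between-cluster variance (BCV)
`sigma_eta^2` and the intraclass correlation ICC =
`sigma_eta^2 / (sigma_eta^2 + sigma_eps^2)` jointly fix the residual
variance:

    sigma_eps^2 = BCV * (1 - ICC) / ICC.

Arms are assigned half/half completely at random (for odd counts the arm
receiving the extra cluster is itself randomized); assignment is
independent of cluster size, mimicking trials where investigators cannot
control enrolment per cluster.

## Effect-size calibration

Each scenario is anchored by `C80`, the cluster count that should give 80%
power at fixed sizes. The effect size is solved from the cluster-level
two-sample comparison (Murray's method):

    Delta^2 = 4 * (sigma_eps^2 + mu * BCV) * (t_{alpha/2} + t_beta)^2 / (mu * C80),

with both t-quantiles on `C80 - 2` degrees of freedom — the degrees of
freedom of a two-sample comparison of cluster means. With alpha = 0.05,
beta = 0.2, mu = 75, ICC = 0.006, BCV = 0.1 and C80 = 60 this gives
Delta = 0.417. `sigma_eps^2 + mu * BCV` is `mu` times the variance of a
cluster mean, so `Delta^2` is the squared difference detectable from
`C80/2` cluster means per arm. The exact noncentral-t power of the
cluster-means test at these settings is 0.8001, i.e. the calibration is
accurate to a fraction of a percentage point, which is why simulated power
at `C_A = C80` sits just below 80%.

## Cluster-size model

Variable cluster sizes are negative binomial (gamma–Poisson, so the
dispersion need not be an integer) with the dispersion pinned by the
requested coefficient of variation:

    r = mu / (mu * cv^2 - 1)   =>   Var = mu + mu^2 / r = (mu * cv)^2.

The study uses cv in {0.5, 1.0, 1.5}; cv = 1.5 is deliberately extreme —
at mu = 20 the raw distribution yields an empty cluster 18% of the time,
50+ participants 12% of the time and 140+ 1% of the time. Because trials
cannot enrol empty clusters, sizes are drawn as `3 + NB(mean = mu - 3, r)`
with `r` recomputed at the pre-shift mean, at every cv level. The shift
keeps the sampled mean exactly at `mu`; the realized cv of the shifted
sizes is slightly below nominal (about 1.28 at mu = 20, cv = 1.5). Whether
the original study computed `r` at the pre-shift or the nominal mean is
ambiguous; the two choices give essentially identical dispersions at the
study's parameter values (r = 0.4564 vs 0.4545 at mu = 20, cv = 1.5), and
the pre-shift reading is used because it preserves the mean exactly.

## Per-trial test

The primary analysis is the linear mixed model with a fixed treatment
effect and a random cluster intercept, fit by REML, with a two-sided Wald
t-test of the treatment coefficient on `K - 2` degrees of freedom
(`K` = number of clusters). Because both fixed-effect covariates are
cluster-constant, the model collapses onto per-cluster sufficient
statistics (size, mean, within-cluster sum of squares) and REML reduces to
a one-dimensional profile over the variance ratio
`lambda = sigma_eta^2 / sigma_eps^2`:

* given `lambda`, the GLS estimate is a weighted regression of cluster
  means with weights `J_k / (1 + lambda * J_k)`;
* the profiled criterion `(N-2) log Q + sum log(1 + lambda J_k) +
  log det(X'WX)` is minimized over `log lambda` in [-30, 12] by bounded
  scalar search, with an explicit check of the `lambda = 0` boundary;
* `sigma_eps^2` is estimated as `Q / (N - 2)` and the Wald statistic uses
  the GLS covariance at the optimum.

This is the exact REML random-intercept solution — the test suite
cross-checks it against `statsmodels` `MixedLM` and verifies the profiled
criterion is never worse than the general-purpose optimizer's — but it is
orders of magnitude faster, which is what makes 5000-replicate power
estimates routine on one core (~1 ms per simulated trial at 60 clusters of
75).

A fast `cluster-means` mode (pooled two-sample t-test on unweighted
per-cluster means, df = K - 2) is also provided, and is used as the
fallback when the mixed-model fit fails (flagged `converged = False`,
never counted as an automatic rejection or acceptance). For balanced
designs it is the same cluster-level analysis as the mixed model —
rejection decisions agree on ≥ 99% of trials — but under heavy size
variability it is badly inefficient (power 0.26 vs 0.66 at cv = 1.5 in the
worked example) because it ignores cluster precision. Power estimation
therefore defaults to the mixed model; the fast mode is for balanced
designs and for fallback.

## Power estimation and required clusters

Fixed-size power at a given actual cluster count `C_A` averages the
rejection indicator over 5000 independent trials (default). Variable-size
power draws a fresh size set per replicate — 2000 size sets, one simulated
trial each — so size variability and outcome variability are averaged
jointly, exactly one trial per size set. The Monte-Carlo standard error is
the binomial `sqrt(p(1-p)/n)`.

A power curve over the `C_A` ladder is interpolated at the 0.8 target by
solving the two-point line through the first adjacent pair with
`P(C_lo) < 0.8 <= P(C_hi)`, scanning left to right. Raw points are used —
no smoothing or isotonic regression — and a non-monotone drop larger than
twice the summed Monte-Carlo errors is logged as a warning. Curves that
start at or above the target, or never reach it, return an explicit
out-of-range status instead of extrapolating. The inflation relative to
the formula anchor is reported as `100 * (C_hat_cv - C80) / C80`.

## Study orchestration

The default grid is 5 mean sizes x 7 ICCs x 3 BCVs x 4 C80 values = 420
scenarios; each is simulated over a `C_A` ladder {5, 10, 15, 20, 40, 60}
extended by 80 when C80 > 10 and by 100 and 120 when C80 > 20, giving
3,255 curve points, each at four variability levels (fixed, cv = 0.5, 1.0,
1.5). Every (scenario, `C_A`, cv) job derives its seed from the master
seed and its grid coordinates, and every replicate inside a job gets its
own spawned substream — results are byte-identical across reruns and
worker counts, and any single replicate can be replayed in isolation.
Interrupted runs resume from the persisted power table. Output is plain
tab-separated text with a schema-version header.

The comparison summary reports, over scenarios with valid crossings (the
rest are counted, never dropped): the correlation and mean difference
between the simulated fixed-size requirement and `C80`; paired-t
differences between successive variability levels (descriptive, at
whatever scale was run); and the median/range of the percent inflation per
cv level.

## Problem sizes and what the tests show

The bundled tests and the acceptance script run the worked-example
scenario at the study's own per-point replicate counts (5000 fixed / 2000
variable) and exercise the full pipeline on reduced grids (hundreds of
replicates per point); full-grid summaries such as the 0.9982 correlation
are population statements about a 68-million-simulation sweep and are
checked only directionally at reduced scale. The synthetic generator *is*
the study's data model, so passing tests demonstrate internal consistency
of calibration, simulation, testing and interpolation — not that real
trials have normal outcomes, negative-binomial enrolment, or
size-independent cluster effects, none of which the generator challenges.

## Known limitations

* Equal-armed, continuous-outcome, parallel designs only: no binary/count
  outcomes, covariates, crossover/matched/baseline-controlled designs, or
  unequal allocation.
* The Wald t with `K - 2` degrees of freedom is one defensible convention;
  Satterthwaite-type degrees of freedom would shift power estimates by
  fractions of a percentage point in unbalanced trials.
* Single published-point comparisons at cv = 1.5 carry the source's own
  Monte-Carlo error (~±0.01 on a 2000-replicate power estimate); the
  package's estimates can sit a percentage point or two from any one
  printed value while agreeing with the underlying curve.
* At `C_A = C80` the true power is ~0.80 by construction, so an
  interpolation bracket must include a point clearly below the target
  (e.g. `C_A = 40` in the worked example) for the 0.8 crossing to be
  well-defined under Monte-Carlo noise.
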