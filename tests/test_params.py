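"""Design-parameter construction and effect-size calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crtsim import ParameterSet, calibrate_effect_size, derive_residual_variance


@pytest.mark.parametrize(
    "icc, bcv, expected",
    [
        (0.006, 0.1, 16.5667),  # the worked-example residual variance
        (0.5, 1.0, 1.0),  # symmetric case: equal variance components
        (0.2, 0.01, 0.04),
    ],
)
def test_residual_variance_values(icc, bcv, expected):
    assert derive_residual_variance(icc, bcv) == pytest.approx(expected, abs=5e-5)


@pytest.mark.parametrize("icc, bcv", [(0.0, 0.1), (1.0, 0.1), (-0.1, 0.1), (0.5, 0.0), (0.5, -1.0)])
def test_residual_variance_domain_errors(icc, bcv):
    with pytest.raises(ValueError):
        derive_residual_variance(icc, bcv)


@given(
    icc=st.floats(1e-4, 1 - 1e-4),
    bcv=st.floats(1e-6, 1e3),
)
@settings(derandomize=True)
def test_icc_round_trip(icc, bcv):
    """ICC = bcv/(bcv + sigma_eps^2) recovers the input to machine precision."""
    se2 = derive_residual_variance(icc, bcv)
    assert bcv / (bcv + se2) == pytest.approx(icc, rel=1e-12)


def test_residual_variance_decreasing_in_icc():
    vals = [derive_residual_variance(icc, 0.5) for icc in (0.01, 0.1, 0.3, 0.9)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_effect_size_worked_example(example_params):
    """The mu=75 / ICC=0.006 / BCV=0.1 / C80=60 scenario needs Delta=0.417."""
    assert round(example_params.delta, 3) == 0.417


def test_effect_size_hand_computed_oracle():
    # frozen from a step-by-step hand evaluation with tabulated t-quantiles
    # (df=8): sigma_eps^2 = 0.8/0.2*1 = 4, Delta^2 = 4*(4+20)*(2.306+0.889)^2/200
    p = ParameterSet(alpha=0.05, mu=20, icc=0.2, bcv=1.0, c80=10)
    assert p.delta == pytest.approx(2.213487, abs=1e-5)


@given(kappa=st.floats(0.1, 10.0))
@settings(derandomize=True, max_examples=25)
def test_effect_size_sqrt_scaling(kappa):
    """Delta^2 is linear in the variance scale: scaling bcv (and hence
    sigma_eps^2, which is proportional to it) by kappa scales Delta by sqrt(kappa)."""
    base = ParameterSet(alpha=0.05, mu=50, icc=0.03, bcv=0.2, c80=20)
    scaled = ParameterSet(alpha=0.05, mu=50, icc=0.03, bcv=0.2 * kappa, c80=20)
    assert scaled.delta == pytest.approx(base.delta * math.sqrt(kappa), rel=1e-12)


def test_effect_size_decreasing_in_c80_and_mu():
    base = dict(alpha=0.05, icc=0.03, bcv=0.1)
    d_c80 = [ParameterSet(mu=50, c80=c, **base).delta for c in (10, 20, 40, 60)]
    assert all(a > b for a, b in zip(d_c80, d_c80[1:]))
    d_mu = [ParameterSet(mu=m, c80=20, **base).delta for m in (20, 50, 75, 100, 125)]
    assert all(a > b for a, b in zip(d_mu, d_mu[1:]))


def test_effect_size_self_consistent_power():
    """Plugging Delta back into the power relation returns 1 - beta analytically.

    The noncentrality of the cluster-means comparison at c80 clusters is
    ncp = Delta * sqrt(mu*c80 / (4*(sigma_eps^2 + mu*bcv))); by construction
    ncp - t_{alpha/2} is the t_{beta} quantile, so its CDF value is 1 - beta.
    """
    p = ParameterSet(alpha=0.05, mu=75, icc=0.006, bcv=0.1, c80=60)
    df = p.c80 - 2
    ncp = p.delta * math.sqrt(p.mu * p.c80 / (4.0 * (p.sigma_eps_sq + p.mu * p.bcv)))
    implied_power = stats.t.cdf(ncp - stats.t.ppf(1 - p.alpha / 2, df), df)
    assert implied_power == pytest.approx(1 - p.beta, rel=1e-12)


def test_non_positive_df_rejected():
    with pytest.raises(ValueError, match="degrees of freedom"):
        ParameterSet(alpha=0.05, mu=20, icc=0.1, bcv=0.1, c80=2)


@pytest.mark.parametrize("bad", [dict(alpha=0.0), dict(alpha=1.0), dict(beta=0.0), dict(mu=3)])
def test_parameter_validation(bad):
    kwargs = dict(alpha=0.05, beta=0.2, mu=20, icc=0.1, bcv=0.1, c80=10)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        ParameterSet(**kwargs)


def test_derived_fields_match_definitions(example_params):
    p = example_params
    assert p.sigma_eps_sq == pytest.approx(derive_residual_variance(p.icc, p.bcv))
    assert p.delta == pytest.approx(calibrate_effect_size(p))
    assert p.delta > 0
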