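import numpy as np
import pytest

from crtsim import ParameterSet


@pytest.fixture(scope="session")
def example_params() -> ParameterSet:
    """The worked example scenario: mu=75, ICC=0.006, BCV=0.1, C80=60."""
    return ParameterSet(alpha=0.05, mu=75, icc=0.006, bcv=0.1, c80=60)


@pytest.fixture(scope="session")
def small_params() -> ParameterSet:
    """A small, fast scenario for simulation-heavy tests."""
    return ParameterSet(alpha=0.05, mu=20, icc=0.03, bcv=0.1, c80=10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
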