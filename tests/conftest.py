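import numpy as np
import pytest

from phenocoop.model_core import ModelParams


@pytest.fixture(scope="session")
def study_params() -> ModelParams:
    """The default study conditions (N=40, r=3.2, g=5, beta=0.1, M=50)."""
    return ModelParams(N=40, r=3.2, g=5, beta=0.1, theta=0.12, M=50, chi_slope=0.1)


@pytest.fixture(scope="session")
def small_params() -> ModelParams:
    """A reduced configuration for simulation-heavy checks."""
    return ModelParams(N=12, r=2.0, g=3, beta=0.1, theta=0.12, M=10, chi_slope=0.1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
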