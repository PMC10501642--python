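import numpy as np
import pytest

from evograph.kernels import MutationKernel

#: the fitness domain used throughout the study conditions
F_MIN, F_MAX = 0.1, 10.0


@pytest.fixture(scope="session")
def uniform_kernel() -> MutationKernel:
    return MutationKernel("uniform", F_MIN, F_MAX)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240911)


def assert_within_se(estimate: float, expected: float, se: float, n_se: float = 3.0, label=""):
    """Assert a Monte-Carlo estimate sits within ``n_se`` standard errors."""
    assert np.isfinite(se) and se > 0, f"invalid SE for {label}"
    z = abs(estimate - expected) / se
    assert z < n_se, f"{label}: estimate {estimate:.5g} vs {expected:.5g} is {z:.2f} SE away"
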