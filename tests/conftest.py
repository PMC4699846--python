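import numpy as np
import pytest

from synturn import ModelParams, PeakParams, build_system


@pytest.fixture(scope="session")
def params7():
    return ModelParams(N=7, b=1e-8)


@pytest.fixture(scope="session")
def params5():
    return ModelParams(N=5, b=1e-8)


@pytest.fixture(scope="session")
def peaks():
    return PeakParams()  # mu=5.0, sigma=1.2, lam=0.05, C=0.1


@pytest.fixture(scope="session")
def system7(params7, peaks):
    return build_system(params7, peaks)


@pytest.fixture(scope="session")
def system5(params5, peaks):
    return build_system(params5, peaks)


@pytest.fixture(scope="session")
def fast_params():
    """Moderate-rate chain: same law as the b=1e-8 system up to time rescaling,
    but with event counts small enough for in-process simulation."""
    return ModelParams(N=5, b=1e-3)


@pytest.fixture(scope="session")
def fast_system(fast_params, peaks):
    return build_system(fast_params, peaks)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
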