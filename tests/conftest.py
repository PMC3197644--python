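import numpy as np
import pytest

from ricepop import (
    GaussianCorrelation,
    NeuronConfig,
    RCFilteredOUCorrelation,
)


@pytest.fixture(scope="session")
def ga_model():
    return GaussianCorrelation(1.0, 10.0)


@pytest.fixture(scope="session")
def ou_model():
    return RCFilteredOUCorrelation(2.0, 5.0, 10.0)


@pytest.fixture(scope="session")
def ga_cfg(ga_model):
    return NeuronConfig(threshold=1.0, tau_m=10.0, voltage_model=ga_model)


@pytest.fixture(scope="session")
def ou_cfg(ou_model):
    return NeuronConfig(threshold=1.0, tau_m=10.0, voltage_model=ou_model)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
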