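import numpy as np
import pytest

from crsim import CardioRespModel, ParameterSet, initialize_steady_state


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def steady(params):
    return initialize_steady_state(params)


@pytest.fixture(scope="session")
def model(params, steady) -> CardioRespModel:
    m = CardioRespModel(params)
    m._steady = steady
    return m


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
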