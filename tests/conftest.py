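import numpy as np
import pytest

from dorsalhorn import (
    CircuitParams,
    DiurnalParams,
    default_circuit_params,
    default_fiber_configs,
)


@pytest.fixture(scope="session")
def params() -> CircuitParams:
    return default_circuit_params()


@pytest.fixture(scope="session")
def diurnal() -> DiurnalParams:
    return DiurnalParams()


@pytest.fixture(scope="session")
def fibers():
    return default_fiber_configs()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
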