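import warnings

import numpy as np
import pytest

import beetlecast as bc


@pytest.fixture(scope="session")
def small_study():
    """A 2+2 synthetic study generated under the published model (seed 11)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bc.generate_study(2, 2, seed=11)


@pytest.fixture(scope="session")
def dev_pairs(small_study):
    return [(e.weather, e.curve) for e in small_study if e.role == "development"]


@pytest.fixture(scope="session")
def val_pairs(small_study):
    return [(e.weather, e.curve) for e in small_study if e.role == "validation"]


@pytest.fixture
def thresholds():
    """The published optimum thresholds: 15 / 21.7 °C."""
    return bc.ThermalThresholds(15.0, 21.7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
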