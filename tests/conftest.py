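import numpy as np
import pytest

from phyloclock.synthetic import (
    load_packaged_calibrations,
    load_packaged_topology,
    load_sweep_topology,
)


@pytest.fixture(scope="session")
def metazoa_topology():
    return load_packaged_topology()


@pytest.fixture(scope="session")
def metazoa_bounds():
    return load_packaged_calibrations()


@pytest.fixture(scope="session")
def sweep_topology():
    return load_sweep_topology()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
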