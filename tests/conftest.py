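import numpy as np
import pytest

import uticea


@pytest.fixture(scope="session")
def evidence():
    return uticea.load_parameters()


@pytest.fixture(scope="session")
def table():
    return uticea.StratificationTable.default()


@pytest.fixture(scope="session")
def point_params(evidence):
    return evidence.point_estimates()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_24)
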