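import numpy as np
import pytest

from extropt import ann
from extropt.design import PAPER_FACTORS, load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def fixture_net():
    return ann.load_fixture_weights()


@pytest.fixture(scope="session")
def paper_factors():
    return PAPER_FACTORS


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
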