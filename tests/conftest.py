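import numpy as np
import pytest

from desopt.design import load_table1, table1_factors
from desopt.rsm import fit_quadratic


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def factors():
    return table1_factors()


@pytest.fixture(scope="session")
def table1_model(table1):
    return fit_quadratic(table1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
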