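import numpy as np
import pytest

from g1crit import RbParams, find_bifurcation, reduce_to_normal_form


@pytest.fixture(scope="session")
def rb():
    return RbParams()


@pytest.fixture(scope="session")
def bifurcation(rb):
    return find_bifurcation(rb)


@pytest.fixture(scope="session")
def reduction(rb):
    return reduce_to_normal_form(rb)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
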