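import pytest

from mitofold import (CONDENSIN_I_BEST_FIT, CONDENSIN_II_BEST_FIT,
                      ChromatidParams)
from mitofold.synthetic import exponential_loop_array


@pytest.fixture(scope="session")
def params_condensin_ii() -> ChromatidParams:
    return ChromatidParams(**CONDENSIN_II_BEST_FIT)


@pytest.fixture(scope="session")
def params_condensin_i() -> ChromatidParams:
    return ChromatidParams(**CONDENSIN_I_BEST_FIT)


@pytest.fixture()
def small_loop_array():
    return exponential_loop_array(20e6, 400e3, seed=1)


@pytest.fixture(autouse=True)
def _silence_expected_warnings(recwarn):
    yield
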