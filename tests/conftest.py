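import numpy as np
import pytest

from tepars.catalog import load_default_catalog
from tepars.synthdata import make_fixture_study


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def fixture_study():
    return make_fixture_study(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
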