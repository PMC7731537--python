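import numpy as np
import pytest

from tcatrace import IsotopeTable, default_pathway, load_fragment_catalog


@pytest.fixture(scope="session")
def pathway():
    return default_pathway()


@pytest.fixture(scope="session")
def isotopes():
    return IsotopeTable.default()


@pytest.fixture(scope="session")
def catalog():
    return load_fragment_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
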