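import numpy as np
import pytest

from pepscreen import load_rules


@pytest.fixture(scope="session")
def trypsin():
    return load_rules(enzymes=["trypsin"])


@pytest.fixture(scope="session")
def trypsin_papain():
    return load_rules(enzymes=["trypsin", "papain"])


@pytest.fixture(scope="session")
def all_rules():
    return load_rules()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
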