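import numpy as np
import pytest

from macpol import load_default_network
from macpol.rules import build_rule_table


@pytest.fixture(scope="session")
def net():
    return load_default_network()


@pytest.fixture(scope="session")
def rules():
    return build_rule_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
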