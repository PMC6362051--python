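import numpy as np
import pytest

from tapairscan.align import default_scheme
from tapairscan.synthetic import antitoxin_seed, toxin_seed


@pytest.fixture(scope="session")
def scheme():
    """BLOSUM62 / 11 / 1 scheme, loaded once per session."""
    return default_scheme()


@pytest.fixture(scope="session")
def toxin():
    return toxin_seed()


@pytest.fixture(scope="session")
def antitoxin():
    return antitoxin_seed()


@pytest.fixture()
def rng():
    return np.random.default_rng(20190204)
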