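import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from cnslim.synthetic import NHE1_FRAGMENTS, nhe1_printed_composite


@pytest.fixture(scope="session")
def nhe1():
    """Printed NHE1 fragments with their own residue numbering."""
    return NHE1_FRAGMENTS


@pytest.fixture(scope="session")
def nhe1_composite():
    return nhe1_printed_composite()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
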