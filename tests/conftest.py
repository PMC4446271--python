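import pytest

from burstrev.params import ISLANDS, SLICES


@pytest.fixture(scope="session")
def islands():
    """Micro-culture parameter set (t_r = 2 s, J = 1.98, L = 0.0054)."""
    return ISLANDS


@pytest.fixture(scope="session")
def slices():
    """Acute-slice parameter set (t_r = 20 s, J = 2.06, L = 0.037)."""
    return SLICES
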