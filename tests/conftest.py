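import numpy as np
import pytest

from ajmech.saim import AngleSweep, LayerStack


@pytest.fixture(scope="session")
def sweep():
    """The standard 14-angle acquisition sweep: 0° to 52° in 4° steps."""
    return AngleSweep()


@pytest.fixture(scope="session")
def layers():
    """488-nm optics over a 500-nm thermal oxide."""
    return LayerStack()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
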