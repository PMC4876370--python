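import numpy as np
import pytest

from mlar1.datagen import Condition, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 10x10 panel from the hardest design cell, fixed seed."""
    return generate_panel(Condition(T=10, N=10, gamma01=-0.6, sigma_u1=0.40), 42)


@pytest.fixture(scope="session")
def medium_panel():
    """A 25x25 panel with moderate positive autocorrelation."""
    return generate_panel(Condition(T=25, N=25, gamma01=0.3, sigma_u1=0.25), 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
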