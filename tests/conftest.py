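import numpy as np
import pytest

from oxytouch import make_block_design, make_montage


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def session_design():
    """Default gentle-touch session: 20 x (30 s + 15 s) at 6.78 Hz."""
    return make_block_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
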