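import numpy as np
import pytest

from neuropong.motor_decoding import make_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layout():
    return make_layout(3)
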