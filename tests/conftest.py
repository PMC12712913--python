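import numpy as np
import pytest

from sonolfp import StimProtocol, standard_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protocol() -> StimProtocol:
    return standard_protocol()


@pytest.fixture
def fast_protocol() -> StimProtocol:
    """Shortened phases for quick session-level tests."""
    return StimProtocol(phase_len=30.0)
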