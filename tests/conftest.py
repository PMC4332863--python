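import numpy as np
import pytest

from tropisim import TropicParams


@pytest.fixture
def s_grid():
    return np.linspace(0.0, 1.0, 201)


@pytest.fixture
def mixed_params():
    """Both tropisms active: B = 1.5, D = 0.5, M = 3."""
    return TropicParams(beta=1.5, gamma=1.0, nu=0.5, A0=0.5, A_P=1.0, L=1.0)
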