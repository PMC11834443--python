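import numpy as np
import pytest

from pepflux.synth import DECTD_PYK_PARAMS, WT_PYK_PARAMS


@pytest.fixture
def wt_params():
    """Wild-type pyruvate-kinase parameter set (regulated enzyme)."""
    return WT_PYK_PARAMS


@pytest.fixture
def dectd_params():
    """ECTD-truncated parameter set (constitutively active enzyme)."""
    return DECTD_PYK_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
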