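import numpy as np
import pytest

from zfrfc import HRFModel, canonical_hrf


@pytest.fixture(scope="session")
def kernel_tr2():
    """Canonical double-gamma HRF sampled at TR = 2 s (unit peak)."""
    return canonical_hrf(HRFModel(tr=2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
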