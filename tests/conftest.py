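import numpy as np
import pytest

from vsdcortex.geometry import default_array


@pytest.fixture(scope="session")
def geometry():
    """The 464-channel array with default layer bands (built once)."""
    return default_array()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
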