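import numpy as np
import pytest

from nodalsim import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140601)
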