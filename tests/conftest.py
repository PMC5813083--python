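import numpy as np
import pytest

from isocoh import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def white_epochs(rng):
    """Independent white-noise ROIs: 200 trials x 2 ROIs x 64 samples."""
    return EpochSet(rng.standard_normal((200, 2, 64)), ("a", "b"), 256.0)
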