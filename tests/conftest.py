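import numpy as np
import pytest

from morra.metrics import ResponseSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def cycling_57():
    """Length-57 sequence cycling 1,2,3,4,5 repeatedly."""
    return ResponseSequence(tuple((i % 5) + 1 for i in range(57)))


@pytest.fixture
def constant_57():
    """57 identical responses."""
    return ResponseSequence((3,) * 57)


@pytest.fixture
def equifrequent_55():
    """55 responses, each alternative exactly 11 times."""
    return ResponseSequence(tuple((i % 5) + 1 for i in range(55)))
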