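import numpy as np
import pytest

from dgcircuit import generate_combinatorial_patterns


@pytest.fixture(scope="session")
def battery7():
    """The full 7-bit combinatorial input battery (128 patterns)."""
    return generate_combinatorial_patterns(7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
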