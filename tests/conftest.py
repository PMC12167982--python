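import itertools

import pytest

from twinmodels import BinaryTrajectory, make_rng


@pytest.fixture
def rng():
    return make_rng(12345)


@pytest.fixture(scope="session")
def all_binary_sequences():
    """Every binary sequence of length 1..8, as trajectories."""
    return [
        BinaryTrajectory(bits)
        for n in range(1, 9)
        for bits in itertools.product((0, 1), repeat=n)
    ]
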