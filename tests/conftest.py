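import random

import pytest

from lossmap.index import build_index
from lossmap.synthetic import random_genome


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture(scope="session")
def small_genome():
    """Two-record 6 kb genome shared by read-level tests."""
    return random_genome(6000, n_records=2, seed=101)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index(small_genome)
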