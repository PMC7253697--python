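import random

import pytest

from kmerpanel import SequenceRecord


def random_seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def small_genome(rng):
    return SequenceRecord(id="g1", bases=random_seq(rng, 600))
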