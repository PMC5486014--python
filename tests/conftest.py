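import numpy as np
import pytest

from cacmir.io_formats import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def random_seq():
    def make(length, seed=0):
        r = np.random.default_rng(seed)
        return "".join(r.choice(list("ACGT"), size=length))

    return make


@pytest.fixture
def record():
    def make(seq, id="seq"):
        return SequenceRecord(id=id, sequence=seq)

    return make
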