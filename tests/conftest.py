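import numpy as np
import pytest

from uidcall.align import Reference
from uidcall.simulate import random_reference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_ref():
    """A fixed 60 bp single-chromosome reference for hand-checked cases."""
    seq = "ACGTACGTACGTTTGCAGGCTAACCGGTTACAGTCAGGATCCAATTGGCCTTAAGGCCAA"
    return Reference({"ref": seq})


@pytest.fixture
def small_ref():
    """A seeded 2 kb random reference for property and oracle tests."""
    return random_reference(2000, seed=777)


@pytest.fixture
def sim_ref():
    """A seeded 20 kb random reference for simulation tests."""
    return random_reference(20000, seed=777)
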