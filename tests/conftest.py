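import numpy as np
import pytest

from permuzyme.motif import (
    build_default_hairpin_core,
    descriptor_from_permutation,
    enumerate_permutations,
)


@pytest.fixture(scope="session")
def model():
    return build_default_hairpin_core()


@pytest.fixture(scope="session")
def perms(model):
    return enumerate_permutations(model, True)


@pytest.fixture(scope="session")
def descriptors(model, perms):
    return {p.canonical_label: descriptor_from_permutation(model, p) for p in perms}


@pytest.fixture(scope="session")
def default_descriptor(descriptors):
    """The nested, unflipped arrangement used for most planted-instance tests."""
    return descriptors["A_nests_B/0/0"]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
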