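import numpy as np
import pytest

from rwrdti.descriptors import descriptor_matrix
from rwrdti.synthetic import generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default modular world: 4 modules x 25 proteins x 5 drugs."""
    return generate_world(rng_seed=11)


@pytest.fixture(scope="session")
def default_descriptors(default_world):
    """1287-dim descriptors for the default world's proteins (computed once)."""
    return descriptor_matrix(default_world.sequences, on_noncanonical="silent")


@pytest.fixture(scope="session")
def small_world():
    """A miniature world for fast structural tests."""
    return generate_world(
        n_modules=3,
        proteins_per_module=10,
        drugs_per_module=3,
        fp_bits=64,
        seq_len_range=(40, 80),
        rng_seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
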