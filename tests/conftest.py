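import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from bivtrans.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared across fast tests."""
    return generate_dataset(SyntheticSpec(n_genes=200, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The default-parameter planted dataset (n_genes=2000, fixed seed)."""
    return generate_dataset(SyntheticSpec(n_genes=2000, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
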