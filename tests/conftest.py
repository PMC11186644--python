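import numpy as np
import pytest

from neosep.mixing import PRETRAIN, build_training_set
from neosep.synthesis import make_source_bank


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bank():
    """Six 10-s source/noise pairs shared across tests (read-only)."""
    return make_source_bank(6, duration_s=10.0, seed=42)


@pytest.fixture(scope="session")
def small_mixtures(small_bank):
    return build_training_set(small_bank, PRETRAIN, seed=7, training=False)
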