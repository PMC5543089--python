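import numpy as np
import pytest

import eventrsa as er
from helpers import make_table, tiny_identity_location_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def full_design():
    """Single-subject, 24 entities x 12 runs, 4 counterbalanced locations."""
    return make_table(24, 12, 4, seed=42)


@pytest.fixture
def tiny_fixture():
    return tiny_identity_location_fixture()


@pytest.fixture(scope="session")
def small_model():
    return er.random_model_matrix(6, seed=11)
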