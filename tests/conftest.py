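import numpy as np
import pytest
from hypothesis import settings

import latentloop as ll

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_gt():
    """Small bistable ground truth shared across tests (read-only)."""
    return ll.make_ground_truth(40, 5, 3, seed=1)


@pytest.fixture(scope="session")
def small_recordings(small_gt):
    return ll.generate_recordings(small_gt, 30, dt=0.01)


@pytest.fixture(scope="session")
def small_basis(small_recordings):
    from latentloop.synthetic import condition_average

    return ll.coding_basis_from_averages(
        condition_average(small_recordings, 0),
        condition_average(small_recordings, 1),
        small_recordings.time,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
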