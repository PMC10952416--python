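import numpy as np
import pytest

from twobox import BoxGeometry, EnsembleConfig, generate_session


@pytest.fixture(scope="session")
def geometry():
    return BoxGeometry()


@pytest.fixture(scope="session")
def small_session(geometry):
    """A 30-cell five-trial session shared by integration-style tests."""
    cfg = EnsembleConfig(n_cells=30, rng_seed=12)
    return generate_session(
        cfg, geometry, seed=100, two_box_duration=900.0, single_duration=420.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
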