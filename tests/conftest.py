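import numpy as np
import pytest
from hypothesis import settings

from sipsense import ProtocolConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_events():
    """3 participants x 3 fills x 3 sizes x 1 rep = 27 events."""
    cfg = ProtocolConfig(
        n_participants=3,
        fill_levels_g=(100.0, 250.0, 400.0),
        repetitions=1,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def full_events():
    """The complete default protocol: 12 x 7 x 3 x 4 = 1008 events."""
    return generate_dataset(ProtocolConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
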