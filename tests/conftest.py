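import numpy as np
import pytest

from burnscar import SceneSpec, make_burn_pair, make_disk_image


@pytest.fixture(scope="session")
def scene_pair():
    """Default synthetic bi-temporal pair with ground truth (seed 0)."""
    return make_burn_pair(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def disk():
    """Noisy two-region disk fixture for the level-set solver."""
    return make_disk_image((64, 64), inside_value=0.8, outside_value=0.2,
                           noise_sd=0.02, seed=0)


@pytest.fixture(scope="session")
def small_pairs():
    """Ten seeded scene pairs at the default 128x128 study size."""
    return [make_burn_pair(SceneSpec(seed=s)) for s in range(10)]
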