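import numpy as np
import pytest

from jellydet import synthetic as sy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def degraded_scenes():
    """20 seeded synthetic scenes after realistic underwater degradation."""
    images = []
    for seed in range(20):
        scene = sy.make_scene(sy.SceneSpec.random(seed))
        images.append(sy.degrade_underwater(scene.image, sy.DegradationSpec.random(seed)))
    return images


@pytest.fixture(scope="session")
def small_scene():
    return sy.make_scene(sy.SceneSpec.random(7, width=64, height=48))
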