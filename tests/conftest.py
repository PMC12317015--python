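import numpy as np
import pytest

from dualgland.scenes import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SceneSpec(height=32, width=32, seed=7))


@pytest.fixture(scope="session")
def scene_batch():
    return [generate_scene(SceneSpec(height=32, width=32, seed=100 + i,
                                     localization_class=i % 19))
            for i in range(8)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
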