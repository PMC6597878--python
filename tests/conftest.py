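import numpy as np
import pytest

from mitoscope.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene_config():
    """Compact frame for fast unit tests (still default palettes)."""
    return SceneConfig(frame_height=256, frame_width=256, n_mitotic=3, n_nonmitotic=4)


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    """One deterministic small frame plus its truth."""
    return generate_scene(small_scene_config, seed=7)


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic full-size frame plus its truth."""
    return generate_scene(SceneConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
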