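import numpy as np
import pytest

from erestrack.config import SceneConfig
from erestrack.simulate import simulate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One small default-style scene with Golgi, rings and free puncta."""
    cfg = SceneConfig(
        field_size_px=(320, 320),
        n_golgi=2,
        n_puncta=24,
        frac_bound=0.5,
        n_frames=3,
        seed=7,
    )
    truth, renderer = simulate_scene(cfg)
    return cfg, truth, renderer


@pytest.fixture(scope="session")
def er_scene():
    """Golgi-free scene used for morphology tests."""
    cfg = SceneConfig(
        field_size_px=(384, 384),
        n_golgi=0,
        frac_bound=0.0,
        n_puncta=60,
        n_frames=1,
        seed=3,
    )
    truth, renderer = simulate_scene(cfg)
    return cfg, truth, renderer


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
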