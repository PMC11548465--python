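import numpy as np
import pytest

from fruitrack.synthetic import SceneConfig, simulate_orchard


@pytest.fixture(scope="session")
def small_scene():
    """A small static clean scene shared by appearance/tracker tests."""
    cfg = SceneConfig(n_apples=10, n_frames=8, texture_seed=11)
    frames, gt = simulate_orchard(cfg)
    return cfg, frames, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
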