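import numpy as np
import pytest
from scipy import ndimage

import strobomech as sm


def make_speckle_texture(shape=(160, 160), seed=0, contrast=25.0, base=120.0):
    """Band-passed random speckle image, the texture class DIC is designed for."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    band = ndimage.gaussian_filter(white, 1.0) - ndimage.gaussian_filter(white, 2.5)
    return (base + contrast * band / band.std()).astype(np.float32)


@pytest.fixture(scope="session")
def speckle():
    return make_speckle_texture()


@pytest.fixture(scope="session")
def small_scene():
    """Reduced two-population scene (sparse enough to keep a blank region)."""
    return sm.two_population_scene(seed=3, shape=(256, 256), n_cells=6, n_beads=40)


@pytest.fixture(scope="session")
def small_sim(small_scene):
    config = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=250)
    return sm.simulate_experiment(small_scene, config)


@pytest.fixture(scope="session")
def small_result(small_sim):
    return sm.analyze_experiment(small_sim)
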