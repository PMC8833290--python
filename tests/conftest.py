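import numpy as np
import pytest
from hypothesis import settings

import cbctqa as q

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rod_render():
    """Noiseless fidelity-rod module on a 0.4 mm grid, with ground truth."""
    return q.render_phantom(q.catphan_rod_module(), q.DegradationSpec(seed=0),
                            q.GridSpec(shape=(400, 400), spacing=(0.4, 0.4, 1.0)))


@pytest.fixture(scope="session")
def uniform_noise_render():
    """Uniform 20 cm module, 5 slices of independent 20 HU white noise."""
    return q.render_phantom(
        q.catphan_uniform_module(), q.DegradationSpec(noise_sigma=20.0, seed=7),
        q.GridSpec(shape=(540, 540), spacing=(0.4, 0.4, 1.0), n_slices=5))


@pytest.fixture(scope="session")
def edge_render_05():
    """Noiseless slanted edge blurred with a 0.5 mm Gaussian PSF."""
    return q.render_edge((3.0, -200.0, 800.0), 0.5, 0.0,
                         q.GridSpec(shape=(512, 512), spacing=(0.4, 0.4, 1.0)))


@pytest.fixture()
def small_volume():
    rng = np.random.default_rng(11)
    vox = rng.integers(-1000, 1000, size=(3, 12, 12)).astype(float)
    return q.ImageVolume(voxels=vox, spacing=(0.5, 0.5, 1.0))


def match_to_truth(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-truth-center distance to the nearest detected center (mm)."""
    d = np.linalg.norm(detected[None, :, :] - truth[:, None, :], axis=2)
    return d.min(axis=1)
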