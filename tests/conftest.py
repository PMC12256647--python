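import numpy as np
import pytest

from coloc3d import generate_coloc_scene, render_scene


@pytest.fixture(scope="session")
def small_scene():
    """10 fully paired reference/candidate pairs plus 5 unpaired candidates
    in a compact box: enough structure for every pipeline stage, fast."""
    return generate_coloc_scene(
        10, 5, bbox=(15.0, 15.0, 6.0), seed=42
    )


@pytest.fixture(scope="session")
def small_grid(small_scene):
    """Noiseless render of ``small_scene`` at a coarse, still-anisotropic
    spacing, kept small for fast segmentation."""
    return render_scene(
        small_scene,
        voxel_spacing=(0.3, 0.12, 0.12),
        psf_sigma=0.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
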