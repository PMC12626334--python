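import numpy as np
import pytest

from azquant.psf import synthetic_gaussian_psf
from azquant.stack_io import VoxelSize
from azquant.synthetic import NoiseModel, SceneConfig, generate_scene, render_stack


@pytest.fixture(scope="session")
def voxel_size():
    return VoxelSize(0.370, 0.079, 0.079)


@pytest.fixture(scope="session")
def small_psf(voxel_size):
    """Compact Gaussian PSF for fast rendering in unit tests."""
    return synthetic_gaussian_psf(
        (0.4, 0.12, 0.12), window=(9, 15, 15), voxel_size=voxel_size
    )


@pytest.fixture(scope="session")
def tiny_scene():
    """A small, well-separated 5-compartment scene with fixed seed."""
    cfg = SceneConfig(
        shape=(16, 48, 100),
        counts=(6, 6, 6, 6, 6),
        min_separation_um=1.2,
        margin_um=(1.2, 0.6, 0.6),
        background=0.0,
        seed=7,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def tiny_render(tiny_scene, small_psf):
    return render_stack(tiny_scene, small_psf, NoiseModel.off())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
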