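import numpy as np
import pytest

from nanobone.optics import OpticsGeometry
from nanobone.phantom import PhantomConfig, generate_phantom


def small_config(**overrides) -> PhantomConfig:
    """48³ phantom at 120 nm voxels — cheap enough for per-test generation."""
    kwargs = dict(
        shape=(48, 48, 48),
        voxel_size_nm=120.0,
        specimen_radius_um=2.6,
        cement_offset_um=0.0,
        cement_thickness_um=0.6,
        n_lacunae_osteonal=1,
        n_lacunae_interstitial=1,
        lacuna_volume_osteonal_um3=0.8,
        lacuna_volume_interstitial_um3=1.0,
        canaliculi_per_lacuna=3,
        interstitial_canaliculi_per_lacuna=1,
        canaliculus_radius_um=(0.15, 0.25),
        canaliculus_max_length_um=1.0,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


def small_geometry(**overrides) -> OpticsGeometry:
    """Two-distance geometry matched to the 120 nm small phantom."""
    kwargs = dict(
        energy_keV=17.0,
        d1_mm=(32.6, 47.6),
        d_total_mm=525.0,
        n_detector=48,
        n_angles=24,
        photons=None,
    )
    kwargs.update(overrides)
    geom = OpticsGeometry(**kwargs)
    return geom.with_common_pixel(120.0)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomConfig(), seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_config(), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
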