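import numpy as np
import pytest

from adipo3d import GeneratorParams, NoiseParams, generate_phantom

# Coarse, small, noise-free-ish phantoms keep unit tests fast; the
# acceptance suite exercises the full-size study conditions.

NOISE_FREE = NoiseParams(photon_scale=0.0, read_sigma=0.0)
NO_OPTICS = dict(psf_sigma=(0.0, 0.0, 0.0), attenuation_length=np.inf, noise=NOISE_FREE)


@pytest.fixture(scope="session")
def five_sphere_phantom():
    """Noise-free, blur-free phantom with 5 well-separated spheres."""
    params = GeneratorParams(
        n_cells=5,
        domain_size=(300.0, 300.0, 160.0),
        volume_mean=150_000.0,
        volume_cv=0.2,
        voxel_size=(2.0, 2.0, 4.0),
        seed=7,
        **NO_OPTICS,
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def noisy_phantom_50():
    """50-cell phantom with default optics/noise at reduced resolution."""
    params = GeneratorParams(
        n_cells=50,
        domain_size=(600.0, 600.0, 250.0),
        volume_mean=200_000.0,
        volume_cv=0.3,
        voxel_size=(3.24, 3.24, 4.0),
        seed=13,
    )
    return generate_phantom(params)


@pytest.fixture
def sphere_mask_r40():
    """Digital sphere of radius 40 voxels on a 100^3 isotropic grid."""
    zz, yy, xx = np.ogrid[:100, :100, :100]
    return ((zz - 50.0) ** 2 + (yy - 50.0) ** 2 + (xx - 50.0) ** 2 <= 40.0**2)


def rasterize_sphere(radius_um, voxel_size, margin_vox=3):
    """Voxel-center rasterization of one sphere, used as an oracle."""
    dx, dy, dz = voxel_size
    n = [int(np.ceil(2 * radius_um / d)) + 2 * margin_vox for d in (dz, dy, dx)]
    center = [(s - 1) / 2.0 * d for s, d in zip(n, (dz, dy, dx))]
    zz, yy, xx = np.ogrid[: n[0], : n[1], : n[2]]
    return (
        (zz * dz - center[0]) ** 2
        + (yy * dy - center[1]) ** 2
        + (xx * dx - center[2]) ** 2
    ) <= radius_um**2
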