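import numpy as np
import pytest

from porespeed.medium import MediumMaps
from porespeed.phantoms import PhantomSpec, generate_phantom

DX = 0.05e-3  # m


@pytest.fixture(scope="session")
def slab_profile_1d():
    """1-D water / bone / water property profile (64 voxels, no phantom)."""
    nz = 64
    c = np.full(nz, 1500.0)
    rho = np.full(nz, 1000.0)
    a = np.zeros(nz)
    c[20:40], rho[20:40], a[20:40] = 3514.0, 1908.0, 109.1
    return MediumMaps(c, rho, a, voxel_size=DX)


@pytest.fixture(scope="session")
def small_phantom_2d():
    """Scaled 2-D phantom: 3.2 x 8 mm, 0.3 mm pores at 25 % porosity."""
    spec = PhantomSpec(pore_diameter=0.3, target_porosity=0.25,
                       extent=(3.2, 8.0), rng_seed=7,
                       porosity_tolerance=0.02)
    return generate_phantom(spec)
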