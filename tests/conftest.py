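import numpy as np
import pytest

from lymphatlas import phantom as ph
from lymphatlas.spatial import RegionMask, VolumeGeometry


@pytest.fixture(scope="session")
def small_geometry() -> VolumeGeometry:
    return VolumeGeometry((24, 24, 20), (2.0, 2.0, 2.5), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def sphere_mask() -> RegionMask:
    """Radius-8 mm sphere centered in a 24 mm cube, unit spacing."""
    geom = VolumeGeometry((24, 24, 24))
    centers = geom.voxel_centers()
    inside = ((centers - 11.5) ** 2).sum(axis=-1) <= 8.0**2
    return RegionMask(geom, inside.astype(np.int32), {1: "sphere"})


@pytest.fixture(scope="session")
def tiny_phantom():
    """Noise-free small phantom: (volume, structures, nodal) tuple."""
    spec = ph.default_phantom_spec(
        dims=(48, 48, 36), spacing=(4.0, 4.0, 5.0), noise_sd=0.0, texture_sd=0.0, seed=5
    )
    return ph.generate_phantom(spec), spec


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Closed 12-triangle surface of the unit cube [0,1]^3."""
    from lymphatlas.spatial import SurfaceMesh

    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    f = np.array([
        [0, 1, 3], [0, 3, 2],       # x = 0
        [4, 7, 5], [4, 6, 7],       # x = 1
        [0, 5, 1], [0, 4, 5],       # y = 0
        [2, 3, 7], [2, 7, 6],       # y = 1
        [0, 2, 6], [0, 6, 4],       # z = 0
        [1, 5, 7], [1, 7, 3],       # z = 1
    ])
    return SurfaceMesh(v, f)
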