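import numpy as np
import pytest

import adipolens as al


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def lattice_scene():
    """Small quasi-ordered slab: 3x3x3 cells, m = 1.03."""
    params = al.GeometryParams((3, 3, 3), 60.0, 10.0, 0.3, seed=4)
    return al.generate_packed_sphere_slab(
        params, al.SlabSpec(210, 210, 210), al.SceneMedium.tissue(1.03))


@pytest.fixture(scope="session")
def single_sphere_scene():
    """One 60 µm adipocyte in air (m = 1.44)."""
    return al.make_single_cell_scene(
        al.SphereSpec(np.zeros(3), 30.0), al.SceneMedium.in_air(1.44))


@pytest.fixture(scope="session")
def sphere_mask():
    """Voxel-rasterized 60 µm sphere at 1 µm pitch."""
    return al.make_fixture_mask("sphere", 60.0, 1.0, seed=0)
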