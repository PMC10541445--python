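"""Shared fixtures: a desk-scale detector, toy particle and ground truth.

Everything is generated programmatically; the desk geometry is a 31 x 31
detector at 45 mm whose q range resolves the speckles of a ~30 A toy
particle with a few pixels per speckle.
"""

import numpy as np
import pytest

from spisim.diffraction import default_volume_grid, generate_dataset, ideal_intensity_volume
from spisim.geometry import DetectorGeometry, build_pixel_map
from spisim.rotations import sample_rotations
from spisim.scatter import make_toy_particle


@pytest.fixture(scope="session")
def desk_geom():
    return DetectorGeometry(
        n_fast=31, n_slow=31, pixel_size_um=1200.0,
        distance_mm=45.0, photon_energy_kev=4.96,
    )


@pytest.fixture(scope="session")
def desk_pixmap(desk_geom):
    return build_pixel_map(desk_geom)


@pytest.fixture(scope="session")
def paper_geom():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def toy_particle():
    return make_toy_particle(40, extent_A=30.0, seed=7)


@pytest.fixture(scope="session")
def desk_grid(desk_pixmap):
    return default_volume_grid(desk_pixmap)


@pytest.fixture(scope="session")
def gt_volume(toy_particle, desk_grid):
    edge, dq = desk_grid
    return ideal_intensity_volume(toy_particle, edge, dq)


@pytest.fixture(scope="session")
def sentinels_500(gt_volume, desk_pixmap):
    """50 held-out 500-photon sentinel patterns from the ground truth."""
    return generate_dataset(
        gt_volume, 50, desk_pixmap, mean_photons=500.0, seed=11,
        meta={"role": "sentinel"},
    )


@pytest.fixture(scope="session")
def rot_level2():
    return sample_rotations(2)


@pytest.fixture(scope="session")
def rot_level4():
    return sample_rotations(4)
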