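"""Shared fixtures: synthetic phantoms are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from i2m.phantom import (
    IntensityModel,
    PrepSpec,
    make_prep_mesh,
    render_intensities,
    voxelize_impression,
)
from i2m.segmentation import fit_calibration

# a "noise-free" render still needs positive class SDs
NOISE_FREE = dict(sd_air=1e-9, sd_pvs=1e-9)


@pytest.fixture(scope="session")
def prep_spec():
    return PrepSpec()


@pytest.fixture(scope="session")
def prep_mesh(prep_spec):
    return make_prep_mesh(prep_spec)


@pytest.fixture(scope="session")
def prep_occupancy(prep_mesh):
    """Default die voxelized at 100 um with partial-volume supersampling."""
    return voxelize_impression(
        prep_mesh, bbox_margin=1.0, spacing=0.1, supersample_factor=2
    )


@pytest.fixture(scope="session")
def prep_gray(prep_occupancy):
    """Default-noise CBCT-like rendering of the die impression."""
    return render_intensities(prep_occupancy, IntensityModel(noise_seed=0))


@pytest.fixture(scope="session")
def prep_gray_noise_free(prep_occupancy):
    return render_intensities(prep_occupancy, IntensityModel(noise_seed=0, **NOISE_FREE))


@pytest.fixture(scope="session")
def pure_two_class_gray(prep_mesh):
    """Binary occupancy (no partial volume) + noise: exactly the two-class
    generative model, used for histogram-shape checks."""
    occ = voxelize_impression(
        prep_mesh, bbox_margin=1.0, spacing=0.1, supersample_factor=1
    )
    return occ, render_intensities(occ, IntensityModel(noise_seed=0))


@pytest.fixture(scope="session")
def reference_phantom():
    """A second die geometry acting as the material-calibration reference."""
    spec = PrepSpec(
        abutment_height=3.5,
        total_convergence_angle=10.0,
        margin_radius=3.2,
        chamfer_depth=0.4,
    )
    mesh = make_prep_mesh(spec)
    occ = voxelize_impression(mesh, bbox_margin=1.0, spacing=0.1, supersample_factor=2)
    return mesh, occ


@pytest.fixture(scope="session")
def calibration_default_noise(reference_phantom):
    mesh, occ = reference_phantom
    gray = render_intensities(occ, IntensityModel(noise_seed=11))
    return fit_calibration(gray, mesh, span=0.9)


@pytest.fixture(scope="session")
def calibration_noise_free(reference_phantom):
    mesh, occ = reference_phantom
    gray = render_intensities(occ, IntensityModel(noise_seed=11, **NOISE_FREE))
    return fit_calibration(gray, mesh, span=0.9)


@pytest.fixture(scope="session")
def unit_sphere():
    """Icosphere with 2562 vertices, radius 1 mm."""
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
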