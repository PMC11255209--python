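"""Shared fixtures: small synthetic bones sized for fast FE solves."""

from __future__ import annotations

import numpy as np
import pytest

import bonefail as bf


@pytest.fixture(scope="session")
def femur_spec() -> bf.PhantomSpec:
    """A small noiseless femur-like phantom on an isotropic 1 mm grid."""
    return bf.PhantomSpec(
        grid_shape=(18, 18, 28),
        spacing=(1.0, 1.0, 1.0),
        bone_kind="femur",
        outer_radius_mm=4.0,
        cortical_thickness_mm=1.5,
        height_mm=20.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def femur_phantom(femur_spec):
    return bf.generate_bone_phantom(femur_spec)


@pytest.fixture(scope="session")
def rod_layout(femur_spec) -> bf.RodLayout:
    return bf.default_rod_layout(femur_spec.grid_shape, femur_spec.spacing, radius_mm=1.5)


@pytest.fixture(scope="session")
def unit_calibration() -> bf.DensityCalibration:
    """slope 0.001 (g/cm^3)/HU through the origin — the default rod layout's line."""
    return bf.DensityCalibration(slope=0.001, intercept=0.0)


@pytest.fixture()
def cube_mask() -> bf.Mask:
    """A 10^3 solid cube centred in a 14^3 grid, isotropic 1 mm."""
    data = np.zeros((14, 14, 14), dtype=np.uint8)
    data[2:12, 2:12, 2:12] = 1
    return bf.Mask(data, (1.0, 1.0, 1.0))


def column_mesh(nx: int, ny: int, nz: int, modulus: float = 10_000.0,
                poisson: float = 0.3, spacing: float = 1.0):
    """Homogeneous prismatic column mesh with a uniform modulus."""
    law = bf.MaterialLaw(kind="femur_power", poisson_ratio=poisson)
    mask = bf.Mask(np.ones((nx, ny, nz), np.uint8), (spacing,) * 3)
    dens = bf.Volume(np.ones((nx, ny, nz)), (spacing,) * 3)
    mesh = bf.build_hex_mesh(mask, dens, law)
    mesh.element_modulus[:] = modulus
    return mesh, law
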