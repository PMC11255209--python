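"""QCT density calibration and density-to-elasticity material laws.

CT intensities (HU) are mapped to bone-equivalent density rho_QCT (g/cm^3)
by an ordinary-least-squares line fitted on calibration-phantom rods of
known density scanned with the patient.  Density then maps to Young's
modulus E through one of two laws:

* femur (power law):      E(MPa) = 14900 * rho_QCT ** 1.86
* vertebra (linear law):  E(MPa) = 3230 * rho_QCT - 34.7

Calibrated densities below zero (air, marrow) are clamped to 0 and the
modulus floored at ``e_floor`` (default 0.01 MPa), so soft-tissue voxels
swept into a mask cannot produce singular or negative-stiffness elements —
over-segmented soft tissue then contributes essentially nothing to the
computed failure load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Volume

__all__ = [
    "DensityCalibration",
    "MaterialLaw",
    "femur_law",
    "vertebra_law",
    "fit_hu_density",
    "hu_to_density",
    "density_to_modulus",
]


@dataclass
class DensityCalibration:
    """Affine HU -> rho_QCT map: ``rho = slope * HU + intercept`` (g/cm^3)."""

    slope: float  # (g/cm^3) per HU
    intercept: float  # g/cm^3
    fit_r2: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("phantom inconsistent: calibration slope must be positive")
        if not (0.0 <= self.fit_r2 <= 1.0 + 1e-12):
            raise ValueError(f"fit_r2 must lie in [0, 1], got {self.fit_r2}")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"slope": self.slope, "intercept": self.intercept, "fit_r2": self.fit_r2},
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "DensityCalibration":
        d = json.loads(Path(path).read_text())
        return cls(slope=d["slope"], intercept=d["intercept"], fit_r2=d.get("fit_r2", 1.0))


@dataclass
class MaterialLaw:
    """Density-to-modulus rule plus plasticity parameters.

    ``kind`` selects the functional form: ``femur_power`` gives
    ``coefficient * rho ** exponent``; ``vertebra_linear`` gives
    ``coefficient * rho + offset``.  The result is floored at ``e_floor``.
    The elastic–perfectly-plastic yield stress per element is
    ``E * yield_strain``.
    """

    kind: str = "femur_power"
    coefficient: float = 14900.0  # MPa
    exponent: float = 1.86  # dimensionless; unused for the linear law
    offset: float = 0.0  # MPa; 0 for the power law
    yield_strain: float = 0.015  # dimensionless
    poisson_ratio: float = 0.3
    e_floor: float = 0.01  # MPa, minimum element modulus

    def __post_init__(self) -> None:
        if self.kind not in ("femur_power", "vertebra_linear"):
            raise ValueError(f"unknown material-law kind {self.kind!r}")
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if self.yield_strain <= 0:
            raise ValueError("yield_strain must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.e_floor <= 0:
            raise ValueError("e_floor must be positive")


def femur_law(**overrides) -> MaterialLaw:
    """The femoral power law E = 14900 rho^1.86 (MPa, rho in g/cm^3)."""
    return MaterialLaw(kind="femur_power", coefficient=14900.0, exponent=1.86,
                       offset=0.0, **overrides)


def vertebra_law(**overrides) -> MaterialLaw:
    """The vertebral linear law E = 3230 rho - 34.7 (MPa, rho in g/cm^3)."""
    return MaterialLaw(kind="vertebra_linear", coefficient=3230.0, exponent=1.0,
                       offset=-34.7, **overrides)


def fit_hu_density(rod_hu_means, rod_densities) -> DensityCalibration:
    """Ordinary-least-squares line through (HU, density) rod pairs."""
    hu = np.asarray(rod_hu_means, dtype=float)
    rho = np.asarray(rod_densities, dtype=float)
    if hu.shape != rho.shape or hu.ndim != 1:
        raise ValueError("rod HU means and densities must be 1-D and equal length")
    if hu.size < 2:
        raise ValueError("need at least 2 rods to fit a calibration line")
    if np.unique(hu).size != hu.size:
        raise ValueError("duplicate rod HU values")
    slope, intercept = np.polyfit(hu, rho, 1)
    resid = rho - (slope * hu + intercept)
    ss_tot = float(np.sum((rho - rho.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    if slope <= 0:
        raise ValueError("phantom inconsistent: fitted slope is not positive")
    return DensityCalibration(slope=float(slope), intercept=float(intercept),
                              fit_r2=min(1.0, max(0.0, r2)))


def hu_to_density(volume: Volume, calibration: DensityCalibration) -> Volume:
    """Voxelwise affine HU -> density map; negative densities clamp to 0."""
    rho = calibration.slope * volume.data + calibration.intercept
    return Volume(np.maximum(rho, 0.0), volume.spacing, volume.origin)


def density_to_modulus(rho, law: MaterialLaw, floor: bool = True):
    """Young's modulus (MPa) for density ``rho`` (g/cm^3, scalar or array).

    ``floor=False`` disables the ``e_floor`` clamp (diagnostic use)."""
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise ValueError("density must be non-negative")
    if law.kind == "femur_power":
        e = law.coefficient * rho_arr**law.exponent
    else:
        e = law.coefficient * rho_arr + law.offset
    if floor:
        e = np.maximum(e, law.e_floor)
    return float(e) if np.isscalar(rho) else e
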