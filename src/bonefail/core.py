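"""Core spatial containers: :class:`Volume` and :class:`Mask`.

Conventions used package-wide:

* voxel indices are 0-based, axis order ``(x, y, z)`` with ``z`` the
  cranio-caudal direction;
* the world position of voxel ``(i, j, k)`` is ``origin + index * spacing``
  (millimetres);
* image volumes carry 32-bit float intensities (HU, normalized units or
  g/cm^3 density), masks carry ``uint8`` values in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "Mask", "load_volume", "load_mask"]


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"expected a length-3 vector, got {arr.size} entries")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class Volume:
    """A 3-D scalar field with voxel spacing and world origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (HU, normalized units, or density in g/cm^3).
    spacing : tuple of float
        Voxel edge lengths in mm per axis; strictly positive.
    origin : tuple of float
        World coordinates (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got {self.data.ndim}-D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent of the grid along each axis (shape * spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)

    def save(self, path: str | Path) -> None:
        """Write as NIfTI-1 with spacing in the header (float32 data)."""
        _save_nifti(self.data.astype(np.float32), self.spacing, self.origin, path)


@dataclass
class Mask:
    """A binary 3-D field aligned to a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got {data.ndim}-D")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = data.astype(np.uint8)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "Mask":
        return Mask(self.data.copy(), self.spacing, self.origin)

    def save(self, path: str | Path) -> None:
        """Write as NIfTI-1 (uint8 0/1) with spacing in the header."""
        _save_nifti(self.data.astype(np.uint8), self.spacing, self.origin, path)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _save_nifti(data: np.ndarray, spacing, origin, path: str | Path) -> None:
    img = nib.Nifti1Image(data, _affine(spacing, origin))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _load_nifti(path: str | Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI image as a :class:`Volume`."""
    data, spacing, origin = _load_nifti(path)
    return Volume(data.astype(np.float32), spacing, origin)


def load_mask(path: str | Path) -> Mask:
    """Read a NIfTI image as a :class:`Mask` (values binarized at 0.5)."""
    data, spacing, origin = _load_nifti(path)
    return Mask((np.asarray(data) > 0.5).astype(np.uint8), spacing, origin)
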