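"""Threshold segmentation, island removal, and morphological perturbation.

``segment_bone`` is a classical, pluggable stand-in for any external
segmentation source — a mask produced elsewhere (e.g. by a trained network)
can be loaded from NIfTI and substituted at any point, since segmentation
and simulation are deliberately decoupled.

``perturb_mask`` implements the erosion/dilation operator used to emulate
under- and over-segmentation in the sensitivity study: iterated binary
morphology with a 6-connected (face-neighbour) structuring element, one
voxel layer per iteration, acting in voxel space (anisotropic spacing is
ignored, matching the "pixels" framing of the perturbation grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Mask, Volume

__all__ = [
    "PerturbationSpec",
    "VARIANT_GRID",
    "segment_bone",
    "postprocess_mask",
    "perturb_mask",
]


def _structuring_element(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)  # face-neighbour cross
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)  # full cube
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass(frozen=True)
class PerturbationSpec:
    """One cell of the perturbation grid: erode/dilate by 0, 1 or 2 layers."""

    op: str = "none"  # "erode" | "dilate" | "none"
    iterations: int = 0
    connectivity: int = 6  # 6 = face-neighbour cross (default), 26 = full cube

    def __post_init__(self) -> None:
        if self.op not in ("erode", "dilate", "none"):
            raise ValueError(f"unknown op {self.op!r}")
        if self.iterations not in (0, 1, 2):
            raise ValueError(f"iterations must be 0, 1 or 2, got {self.iterations}")
        _structuring_element(self.connectivity)

    @property
    def label(self) -> str:
        if self.op == "none" or self.iterations == 0:
            return "none"
        return f"{self.op}{self.iterations}"


#: the five perturbation variants of the sensitivity study, strongest erosion first
VARIANT_GRID: tuple[PerturbationSpec, ...] = (
    PerturbationSpec("erode", 2),
    PerturbationSpec("erode", 1),
    PerturbationSpec("none", 0),
    PerturbationSpec("dilate", 1),
    PerturbationSpec("dilate", 2),
)


def segment_bone(
    volume: Volume, hu_threshold: float = 170.0, min_component_voxels: int = 50
) -> Mask:
    """Threshold segmentation: voxels >= ``hu_threshold``, holes filled,
    then only connected components of at least ``min_component_voxels``
    retained.  Expects intensities in HU (not normalized units)."""
    fg = volume.data >= hu_threshold
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n > 0:
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_component_voxels)
        keep = keep[keep != 0]
        fg = np.isin(labels, keep)
    if not fg.any():
        raise ValueError(f"no bone found at threshold {hu_threshold} HU")
    return Mask(fg.astype(np.uint8), volume.spacing, volume.origin)


def postprocess_mask(mask: Mask, min_island_voxels: int = 50, connectivity: int = 6) -> Mask:
    """Island-removal post-processing: a morphological opening (one erosion
    followed by one dilation) and removal of residual components smaller
    than ``min_island_voxels``.  Empty input yields empty output."""
    st = _structuring_element(connectivity)
    data = mask.data.astype(bool)
    opened = ndimage.binary_dilation(ndimage.binary_erosion(data, st), st)
    labels, n = ndimage.label(opened)
    if n > 0:
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_island_voxels)
        keep = keep[keep != 0]
        opened = np.isin(labels, keep)
    return Mask(opened.astype(np.uint8), mask.spacing, mask.origin)


def perturb_mask(mask: Mask, spec: PerturbationSpec) -> Mask:
    """Apply the perturbation ``spec``: iterated erosion or dilation, one
    voxel layer per iteration.  ``op == "none"`` or zero iterations is the
    identity.  Erosion that empties the mask is an error."""
    if spec.op == "none" or spec.iterations == 0:
        return mask.copy()
    st = _structuring_element(spec.connectivity)
    data = mask.data.astype(bool)
    if spec.op == "erode":
        out = ndimage.binary_erosion(data, st, iterations=spec.iterations)
        if not out.any():
            raise ValueError("mask vanished under erosion")
    else:
        out = ndimage.binary_dilation(data, st, iterations=spec.iterations)
    return Mask(out.astype(np.uint8), mask.spacing, mask.origin)
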