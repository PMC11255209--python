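"""Pre-processing chain for bilateral CT volumes.

The chain standardizes acquisitions before segmentation: resampling to a
common voxel size, splitting a hip volume into its two femurs, mirroring
the left femur so all bones share one handedness, affine co-registration
to a reference bone, and per-volume intensity normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import Mask, Volume

__all__ = [
    "AffineTransform",
    "resample",
    "flip_lr",
    "split_and_flip",
    "register_affine",
    "normalize_intensity",
]


@dataclass
class AffineTransform:
    """World-space affine mapping moving-image coordinates into the
    reference frame: ``x_ref = matrix @ x_mov + translation`` (mm)."""

    matrix: np.ndarray  # 3x3 linear part
    translation: np.ndarray  # 3-vector, mm
    improved: bool = True  # False when the optimizer failed to improve on identity

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    def displacement_at(self, point) -> np.ndarray:
        """Displacement the transform applies at a world point (mm) —
        the meaningful translation measure for a general affine."""
        p = np.asarray(point, dtype=float).reshape(3)
        return self.matrix @ p + self.translation - p

    def as_homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        h[:3, :3] = self.matrix
        h[:3, 3] = self.translation
        return h

    @classmethod
    def identity(cls, improved: bool = True) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), improved=improved)


def resample(
    volume: Volume | Mask,
    target_spacing: tuple[float, float, float],
    interpolation: str | None = None,
) -> Volume | Mask:
    """Resample onto a grid of the requested voxel size.

    The output shape per axis is ``round(extent_mm / target_spacing)``
    (minimum 1) and the grid edges of input and output coincide, so the
    world extent is preserved to within one voxel.  Masks are always
    resampled with nearest-neighbour; images default to linear.
    """
    target = tuple(float(s) for s in np.asarray(target_spacing).reshape(3))
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    is_mask = isinstance(volume, Mask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    if is_mask and interpolation != "nearest":
        raise ValueError("masks must be resampled with nearest-neighbour")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    shape_out = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(volume.shape, volume.spacing, target)
    )
    # cell-centred grids with coincident outer edges:
    # input index coordinate of output voxel i is (i*t + (t - s)/2) / s
    coords = np.meshgrid(
        *[
            (np.arange(m) * t + (t - s) / 2.0) / s
            for m, t, s in zip(shape_out, target, volume.spacing)
        ],
        indexing="ij",
    )
    order = 1 if interpolation == "linear" else 0
    data = ndimage.map_coordinates(
        volume.data.astype(np.float32), np.stack(coords), order=order, mode="nearest"
    )
    origin = tuple(o + (t - s) / 2.0 for o, t, s in zip(volume.origin, target, volume.spacing))
    if is_mask:
        return Mask(np.rint(data).astype(np.uint8), target, origin)
    return Volume(data, target, origin)


def flip_lr(volume: Volume | Mask) -> Volume | Mask:
    """Mirror about the left-right (x) axis; an involution."""
    cls = Mask if isinstance(volume, Mask) else Volume
    return cls(volume.data[::-1].copy(), volume.spacing, volume.origin)


def split_and_flip(
    volume: Volume,
    mask_pair_hint: tuple[Mask, Mask] | None = None,
    bone_threshold_hu: float = 170.0,
) -> tuple[Volume, Volume]:
    """Split a bilateral volume into two single-bone volumes and mirror the
    left one so both share the right-side handedness.

    The split plane is the mid-gap between the two components' x-extents;
    left/right are identified by world x-coordinate.  Returns
    ``(left_flipped, right)``.
    """
    if mask_pair_hint is not None:
        boxes = []
        for m in mask_pair_hint:
            xs = np.nonzero(m.data.any(axis=(1, 2)))[0]
            if xs.size == 0:
                raise ValueError("empty mask in mask_pair_hint")
            boxes.append((xs[0], xs[-1]))
    else:
        labels, n = ndimage.label(volume.data >= bone_threshold_hu)
        if n != 2:
            raise ValueError(f"expected exactly 2 bone components, found {n}")
        boxes = []
        for lab in (1, 2):
            xs = np.nonzero((labels == lab).any(axis=(1, 2)))[0]
            boxes.append((xs[0], xs[-1]))
    boxes.sort(key=lambda b: b[0])
    if boxes[0][1] >= boxes[1][0]:
        raise ValueError("bone components overlap along x; cannot split")
    split = int(boxes[0][1] + boxes[1][0] + 1) // 2  # mid-gap voxel index
    sp, org = volume.spacing, volume.origin
    left = Volume(volume.data[:split].copy(), sp, org)
    right_origin = (org[0] + split * sp[0], org[1], org[2])
    right = Volume(volume.data[split:].copy(), sp, right_origin)
    return flip_lr(left), right


def _to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T).astype(np.float32))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def _mse(a: sitk.Image, b: sitk.Image) -> float:
    arr_a = sitk.GetArrayViewFromImage(a)
    arr_b = sitk.GetArrayViewFromImage(b)
    return float(np.mean((arr_a - arr_b) ** 2))


def register_affine(moving: Volume, reference: Volume) -> tuple[AffineTransform, Volume]:
    """Affine co-registration of ``moving`` onto ``reference``.

    Mean-squares metric, 3-level multi-resolution pyramid, regular-step
    gradient descent, linear interpolation.  Returns the recovered affine
    (moving -> reference, world mm) and the moving volume resampled into
    the reference grid.  If optimization fails to improve on identity, the
    identity transform is returned with ``improved=False``.
    """
    for name, v in (("moving", moving), ("reference", reference)):
        if float(np.std(v.data)) == 0.0:
            raise ValueError(f"{name} volume has constant intensity; cannot register")

    fixed = _to_sitk(reference)
    mov = _to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        fixed, mov, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=200, relaxationFactor=0.5
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        final = reg.Execute(fixed, mov)
    except RuntimeError:
        warnings.warn("affine registration failed; returning identity", stacklevel=2)
        return AffineTransform.identity(improved=False), resample_into(moving, reference)

    resampled = sitk.Resample(mov, fixed, final, sitk.sitkLinear, float(np.min(moving.data)))
    before = _mse(fixed, sitk.Resample(mov, fixed, sitk.Transform(), sitk.sitkLinear,
                                       float(np.min(moving.data))))
    after = _mse(fixed, resampled)
    if after > before:
        warnings.warn("registration did not improve similarity; returning identity",
                      stacklevel=2)
        return AffineTransform.identity(improved=False), resample_into(moving, reference)

    # sitk's transform maps reference points to moving points; report the
    # inverse, i.e. the map carrying moving-image coordinates into the
    # reference frame.
    try:
        flat = sitk.AffineTransform(final)
    except Exception:
        flat = sitk.AffineTransform(sitk.CompositeTransform(final).GetNthTransform(0))
    M = np.array(flat.GetMatrix()).reshape(3, 3)
    c = np.array(flat.GetCenter())
    t = np.array(flat.GetTranslation())
    # forward map: y = M (x - c) + c + t
    offset = c + t - M @ c
    Minv = np.linalg.inv(M)
    out = Volume(
        sitk.GetArrayFromImage(resampled).T.copy(), reference.spacing, reference.origin
    )
    return AffineTransform(Minv, -Minv @ offset), out


def resample_into(moving: Volume, reference: Volume) -> Volume:
    """Resample ``moving`` onto the reference grid with the identity map."""
    fixed = _to_sitk(reference)
    mov = _to_sitk(moving)
    res = sitk.Resample(mov, fixed, sitk.Transform(), sitk.sitkLinear, float(np.min(moving.data)))
    return Volume(sitk.GetArrayFromImage(res).T.copy(), reference.spacing, reference.origin)


def normalize_intensity(volume: Volume) -> Volume:
    """Per-volume z-score: output has mean 0 and unit SD over all voxels."""
    sd = float(np.std(volume.data))
    if sd == 0.0:
        raise ValueError("cannot normalize a zero-variance volume")
    data = (volume.data - float(np.mean(volume.data))) / sd
    return Volume(data, volume.spacing, volume.origin)
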