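"""Synthetic CT bone phantoms with known geometry and intensities.

Generates femur-like and vertebra-like objects on a regular voxel grid so
that every downstream stage (segmentation, calibration, meshing, solving)
can be exercised against exact analytic oracles instead of clinical scans.

Geometry is analytic — tubes/cylinders with a hemispherical femoral-head
cap — and voxel membership is decided by a voxel-centre-in-solid test, so
voxel counts can be checked by brute force.  With ``noise_sd = 0`` every
voxel's intensity equals the mean of its tissue class, and a fixed
``(spec, seed)`` pair yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Mask, Volume

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "RodSpec",
    "RodLayout",
    "default_rod_layout",
    "measure_rod_means",
    "generate_bone_phantom",
    "generate_hip_volume",
    "embed_rods",
]

_AXES = "xyz"


@dataclass
class PhantomSpec:
    """Parameters of a single synthetic bone.

    Default HU means are plausible CT values: dense cortical bone 1200,
    trabecular bone 300, marrow 0, soft tissue 40.  Default spacing is the
    anisotropic 0.78 x 0.78 x 0.67 mm grid the pipeline standardizes on.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 96)
    spacing: tuple[float, float, float] = (0.78, 0.78, 0.67)
    bone_kind: str = "femur"  # "femur" (tube + hemispherical head) | "vertebra" (shell + core)
    outer_radius_mm: float = 12.0
    cortical_thickness_mm: float = 3.0
    height_mm: float = 50.0
    marrow_radius_fraction: float = 0.35  # shaft marrow-cavity radius / outer radius
    hu_cortical: float = 1200.0
    hu_trabecular: float = 300.0
    hu_marrow: float = 0.0
    hu_soft_tissue: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.bone_kind not in ("femur", "vertebra"):
            raise ValueError(f"unknown bone_kind {self.bone_kind!r}")
        if not (0 < self.cortical_thickness_mm < self.outer_radius_mm):
            raise ValueError(
                "cortical_thickness_mm must lie in (0, outer_radius_mm); got "
                f"{self.cortical_thickness_mm} vs {self.outer_radius_mm}"
            )
        hu = (self.hu_cortical, self.hu_trabecular, self.hu_marrow, self.hu_soft_tissue)
        if not np.all(np.isfinite(hu)):
            raise ValueError("HU means must be finite")
        if not (self.hu_cortical > self.hu_trabecular > self.hu_soft_tissue):
            raise ValueError("need hu_cortical > hu_trabecular > hu_soft_tissue")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # geometry must fit with a one-voxel background margin on every axis
        need = (
            2 * self.outer_radius_mm,
            2 * self.outer_radius_mm,
            self.height_mm,
        )
        for ax in range(3):
            avail = (self.grid_shape[ax] - 2) * self.spacing[ax]
            if need[ax] > avail:
                raise ValueError(
                    f"bone extent {need[ax]:.2f} mm exceeds grid capacity "
                    f"{avail:.2f} mm along axis {_AXES[ax]}"
                )


@dataclass
class LesionSpec:
    """A spherical osteolytic lesion: intensity replaced inside the bone."""

    center: tuple[int, int, int]  # voxel coordinates
    radius_mm: float
    hu_lesion: float = -20.0

    def validate(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius_mm must be positive")


@dataclass
class RodSpec:
    """One calibration rod: a cylinder of known equivalent density."""

    center: tuple[int, int, int]  # voxel coordinates of the rod axis midpoint
    radius_mm: float
    density_g_cm3: float
    hu_mean: float


@dataclass
class RodLayout:
    """Calibration-rod arrangement (rods run along ``orientation``)."""

    rods: list[RodSpec] = field(default_factory=list)
    orientation: int = 2  # axis index along which rods run
    length_mm: float | None = None  # None -> rods span the whole grid

    def validate(self) -> None:
        if len(self.rods) < 2:
            raise ValueError("a calibration layout needs at least 2 rods")
        dens = [r.density_g_cm3 for r in self.rods]
        if not all(b > a for a, b in zip(dens, dens[1:])):
            raise ValueError("rod densities must be strictly increasing")

    @property
    def hu_means(self) -> list[float]:
        return [r.hu_mean for r in self.rods]

    @property
    def densities(self) -> list[float]:
        return [r.density_g_cm3 for r in self.rods]


def default_rod_layout(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radius_mm: float = 4.0,
    y_index: int | None = None,
) -> RodLayout:
    """Five rods spanning 0-800 HU (0-0.8 g/cm^3), laid out along x at a
    fixed y row, running the full z extent of the grid."""
    nx, ny, nz = grid_shape
    y = ny - max(2, int(np.ceil(radius_mm / spacing[1])) + 1) if y_index is None else y_index
    xs = np.linspace(0.15, 0.85, 5) * nx
    rods = [
        RodSpec((int(x), y, nz // 2), radius_mm, rho, hu)
        for x, rho, hu in zip(xs, (0.0, 0.2, 0.4, 0.6, 0.8), (0.0, 200.0, 400.0, 600.0, 800.0))
    ]
    return RodLayout(rods=rods, orientation=2)


def _voxel_centers(shape, spacing):
    """World coordinates of voxel centres along each axis (origin at 0)."""
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _bone_fields(spec: PhantomSpec):
    """Return (mask, tissue HU field) for the noiseless bone on its grid."""
    xs, ys, zs = _voxel_centers(spec.grid_shape, spec.spacing)
    cx = xs[-1] / 2.0
    cy = ys[-1] / 2.0
    z0 = (zs[-1] - spec.height_mm) / 2.0
    z1 = z0 + spec.height_mm
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    r = np.hypot(X - cx, Y - cy)

    R = spec.outer_radius_mm
    t = spec.cortical_thickness_mm

    if spec.bone_kind == "femur":
        # shaft: tube from z0 to z1 - R, capped by a hemispherical head
        shaft_top = z1 - R
        in_shaft = (r <= R) & (Z >= z0) & (Z <= shaft_top)
        d_head = np.sqrt((r) ** 2 + (Z - shaft_top) ** 2)
        in_head = (d_head <= R) & (Z > shaft_top)
        bone = in_shaft | in_head
        # distance to the outer surface (shaft wall or head sphere)
        dist_out = np.where(in_head, R - d_head, R - r)
        cortical = bone & (dist_out <= t)
        # marrow cavity fully enclosed by bone (inset from the distal end and
        # from the head), as in a real medullary canal
        marrow = (
            in_shaft
            & (r <= spec.marrow_radius_fraction * R)
            & (Z >= z0 + t)
            & (Z <= shaft_top - t)
        )
        interior = bone & ~cortical
        hu = np.full(spec.grid_shape, spec.hu_soft_tissue, dtype=np.float32)
        hu[interior] = spec.hu_trabecular
        hu[marrow & interior] = spec.hu_marrow
        hu[cortical] = spec.hu_cortical
    else:  # vertebra-like: cylinder, cortical shell (walls + endplates) + trabecular core
        bone = (r <= R) & (Z >= z0) & (Z <= z1)
        dist_out = np.minimum(R - r, np.minimum(Z - z0, z1 - Z))
        cortical = bone & (dist_out <= t)
        hu = np.full(spec.grid_shape, spec.hu_soft_tissue, dtype=np.float32)
        hu[bone & ~cortical] = spec.hu_trabecular
        hu[cortical] = spec.hu_cortical

    return bone, hu


def generate_bone_phantom(
    spec: PhantomSpec, lesions: list[LesionSpec] | None = None
) -> tuple[Volume, Mask]:
    """Generate one synthetic bone: CT-like volume plus ground-truth mask.

    Lesions replace intensities inside the bone (the mask is unchanged);
    additive Gaussian noise of SD ``spec.noise_sd`` HU is applied last.
    """
    spec.validate()
    bone, hu = _bone_fields(spec)

    for les in lesions or []:
        les.validate()
        xs, ys, zs = _voxel_centers(spec.grid_shape, spec.spacing)
        c = np.array([xs[les.center[0]], ys[les.center[1]], zs[les.center[2]]])
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        sphere = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= les.radius_mm**2
        if not bone[les.center]:
            raise ValueError(f"lesion centre {les.center} lies outside the bone")
        if np.any(sphere & ~bone):
            raise ValueError(
                f"lesion at {les.center} (radius {les.radius_mm} mm) extends outside the bone"
            )
        hu[sphere] = les.hu_lesion

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)

    return Volume(hu, spec.spacing), Mask(bone.astype(np.uint8), spec.spacing)


def generate_hip_volume(
    left_spec: PhantomSpec, right_spec: PhantomSpec, gap_mm: float = 20.0
) -> tuple[Volume, Mask, Mask]:
    """A hip-like acquisition: two femurs in one volume, separated along x.

    The left bone is the mirror image (about x) of its spec's phantom, so a
    pair of identical specs produces a bilaterally symmetric volume.  Returns
    the combined volume and the two per-bone masks (left first), each on the
    combined grid.
    """
    if left_spec.spacing != right_spec.spacing:
        raise ValueError("left and right specs must share voxel spacing")
    if gap_mm <= 0:
        raise ValueError("bones overlap: gap_mm must be positive")
    vol_l, mask_l = generate_bone_phantom(left_spec)
    vol_r, mask_r = generate_bone_phantom(right_spec)
    sp = left_spec.spacing
    gap_vox = int(np.ceil(gap_mm / sp[0]))

    ny = max(vol_l.shape[1], vol_r.shape[1])
    nz = max(vol_l.shape[2], vol_r.shape[2])

    def pad(a, fill):
        out = np.full((a.shape[0], ny, nz), fill, dtype=a.dtype)
        out[:, : a.shape[1], : a.shape[2]] = a
        return out

    hu_fill = np.float32(left_spec.hu_soft_tissue)
    left_img = pad(vol_l.data, hu_fill)[::-1]  # mirror about the left-right axis
    left_msk = pad(mask_l.data, np.uint8(0))[::-1]
    right_img = pad(vol_r.data, np.float32(right_spec.hu_soft_tissue))
    right_msk = pad(mask_r.data, np.uint8(0))

    gap_img = np.full((gap_vox, ny, nz), hu_fill, dtype=np.float32)
    gap_msk = np.zeros((gap_vox, ny, nz), dtype=np.uint8)

    img = np.concatenate([left_img, gap_img, right_img], axis=0)
    lmask = np.concatenate([left_msk, gap_msk, np.zeros_like(right_msk)], axis=0)
    rmask = np.concatenate([np.zeros_like(left_msk), gap_msk, right_msk], axis=0)
    if np.any(lmask & rmask):
        raise ValueError("bones overlap in the combined volume")

    noise_sd = max(left_spec.noise_sd, right_spec.noise_sd)
    if noise_sd > 0:
        # re-noise the combined volume from the left spec's seed so the two
        # halves do not share a noise pattern
        base_l, _ = generate_bone_phantom(replace(left_spec, noise_sd=0.0))
        base_r, _ = generate_bone_phantom(replace(right_spec, noise_sd=0.0))
        img = np.concatenate(
            [pad(base_l.data, hu_fill)[::-1], gap_img, pad(base_r.data, hu_fill)], axis=0
        )
        rng = np.random.default_rng(left_spec.seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)

    return Volume(img, sp), Mask(lmask, sp), Mask(rmask, sp)


def _rod_region(volume: Volume, layout: RodLayout, rod: RodSpec) -> np.ndarray:
    """Boolean field of the voxels inside one rod's cylinder."""
    xs, ys, zs = _voxel_centers(volume.shape, volume.spacing)
    ax = layout.orientation
    axes_r = [a for a in range(3) if a != ax]
    coords = [xs, ys, zs]
    grids = np.meshgrid(xs, ys, zs, indexing="ij")
    c = [coords[a][rod.center[a]] for a in range(3)]
    r2 = (grids[axes_r[0]] - c[axes_r[0]]) ** 2 + (grids[axes_r[1]] - c[axes_r[1]]) ** 2
    inside = r2 <= rod.radius_mm**2
    if layout.length_mm is not None:
        inside &= np.abs(grids[ax] - c[ax]) <= layout.length_mm / 2.0
    return inside


def measure_rod_means(volume: Volume, layout: RodLayout) -> list[float]:
    """Mean intensity inside each rod region — the HU samples fed to the
    density-calibration fit."""
    means = []
    for rod in layout.rods:
        inside = _rod_region(volume, layout, rod)
        if not np.any(inside):
            raise ValueError(f"rod at {rod.center} does not intersect the grid")
        means.append(float(volume.data[inside].mean()))
    return means


def embed_rods(
    volume: Volume,
    layout: RodLayout,
    bone_mask: Mask | None = None,
) -> Volume:
    """Paint calibration rods into a copy of ``volume``.

    Rod voxels are set to each rod's ``hu_mean``; all other voxels are left
    untouched.  If ``bone_mask`` is given, a rod intersecting the bone is an
    error.  An empty layout returns the volume unchanged.
    """
    out = volume.copy()
    if not layout.rods:
        return out
    for rod in layout.rods:
        inside = _rod_region(volume, layout, rod)
        if not np.any(inside):
            raise ValueError(f"rod at {rod.center} does not fit inside the grid")
        if bone_mask is not None and np.any(inside & (bone_mask.data > 0)):
            raise ValueError(f"rod at {rod.center} intersects the bone")
        out.data[inside] = rod.hu_mean
    return out
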