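"""Voxel-based hexahedral finite elements and the nonlinear failure solve.

Every in-mask voxel becomes one 8-node trilinear brick element, nodes
shared between neighbouring voxels.  Each element carries the density of
its voxel and a Young's modulus from the configured material law.  Loading
is displacement-controlled quasi-static axial compression: the nodes in a
thin layer at the top of the bone are driven axially while the bottom
layer is fully constrained.  The constitutive model is small-strain linear
elastic – perfectly plastic (J2 / von Mises) with per-element yield stress
``sigma_y = E * yield_strain``; each increment is equilibrated by Newton
iteration with a consistent tangent and a direct sparse factorization.

Units: lengths mm, moduli MPa (N/mm^2), forces N.  Compressive reaction
loads are reported positive.

The femoral failure load is the maximum reaction over the loading history;
the vertebral failure load is the reaction at the step where the applied
displacement reaches 1.9% of the vertebral height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .calibrate import MaterialLaw, density_to_modulus
from .core import Mask, Volume

__all__ = [
    "HexMesh",
    "BoundaryConditions",
    "SolveResult",
    "build_hex_mesh",
    "element_stiffness",
    "apply_axial_compression_bc",
    "solve_nonlinear",
    "failure_load",
    "VERTEBRA_HEIGHT_STRAIN",
]

#: vertebral failure criterion: height-reduction ratio at which failure is declared
VERTEBRA_HEIGHT_STRAIN = 0.019

_GAUSS = 1.0 / np.sqrt(3.0)
# local corner offsets in VTK hexahedron order
_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]]
)


@dataclass
class HexMesh:
    """One hexahedral element per in-mask voxel, with per-element materials."""

    nodes: np.ndarray  # (n_nodes, 3) world coordinates, mm
    elements: np.ndarray  # (n_elem, 8) node indices, VTK order
    element_density: np.ndarray  # (n_elem,) g/cm^3
    element_modulus: np.ndarray  # (n_elem,) MPa
    voxel_dims: tuple[float, float, float]  # mm

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def save_vtk(self, path: str | Path) -> None:
        """Write the mesh as legacy-ASCII VTK with per-cell density/modulus."""
        lines = ["# vtk DataFile Version 3.0", "bonefail hexahedral mesh", "ASCII",
                 "DATASET UNSTRUCTURED_GRID", f"POINTS {self.n_nodes} float"]
        lines += [" ".join(f"{c:.6g}" for c in p) for p in self.nodes]
        lines.append(f"CELLS {self.n_elements} {self.n_elements * 9}")
        lines += ["8 " + " ".join(str(i) for i in e) for e in self.elements]
        lines.append(f"CELL_TYPES {self.n_elements}")
        lines += ["12"] * self.n_elements
        lines.append(f"CELL_DATA {self.n_elements}")
        for name, arr in (("density", self.element_density), ("modulus", self.element_modulus)):
            lines += [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
            lines += [f"{v:.6g}" for v in arr]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class BoundaryConditions:
    """Displacement-controlled axial compression."""

    fixed_nodes: np.ndarray  # zero displacement on all axes (or axial only, see support)
    driven_nodes: np.ndarray  # prescribed axial displacement
    axis: int = 2
    step_mm: float = 0.05
    max_mm: float = 1.0
    #: "clamped": fixed nodes constrained on all axes (the bone simulations);
    #: "roller": fixed nodes constrained axially only, plus minimal 3-2-1
    #: lateral constraints — the frictionless-platen idealization under which
    #: homogeneous columns match the closed-form uniaxial solution exactly.
    support: str = "clamped"

    def __post_init__(self) -> None:
        if self.support not in ("clamped", "roller"):
            raise ValueError(f"unknown support mode {self.support!r}")
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.driven_nodes = np.asarray(self.driven_nodes, dtype=np.int64)
        if self.fixed_nodes.size == 0 or self.driven_nodes.size == 0:
            raise ValueError("fixed and driven node sets must be nonempty")
        if np.intersect1d(self.fixed_nodes, self.driven_nodes).size:
            raise ValueError("fixed and driven node sets must be disjoint")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.max_mm < self.step_mm:
            raise ValueError("max_mm must be at least step_mm")


@dataclass
class SolveResult:
    """Load–displacement history of one displacement-controlled solve."""

    displacements: np.ndarray  # applied compressive displacement per step, mm
    reactions: np.ndarray  # compressive reaction per step, N (positive)
    failure_load: float = np.nan  # N; filled by failure_load()
    failure_step: int = -1
    criterion: str = ""

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step,displacement_mm,reaction_N\n")
            for i, (d, r) in enumerate(zip(self.displacements, self.reactions)):
                fh.write(f"{i},{d:.6g},{r:.6g}\n")


def build_hex_mesh(mask: Mask, density: Volume, law: MaterialLaw) -> HexMesh:
    """Mesh every in-mask voxel as one hexahedral element.

    Element density is the voxel's density value; the modulus comes from
    ``law`` (floored at ``law.e_floor``).  A disconnected mask triggers a
    warning and only the largest 6-connected component is meshed, so eroded
    masks that fragment still produce a solvable model.
    """
    if mask.shape != density.shape or mask.spacing != density.spacing:
        raise ValueError("mask and density volume must share grid and spacing")
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("cannot mesh an empty mask")
    labels, n = ndimage.label(data, ndimage.generate_binary_structure(3, 1))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        warnings.warn(
            f"mask has {n} connected components; keeping the largest "
            f"({counts.max()} of {data.sum()} voxels)",
            stacklevel=2,
        )
        data = labels == keep

    vox = np.argwhere(data)  # (ne, 3)
    corners = vox[:, None, :] + _CORNERS[None, :, :]  # (ne, 8, 3)
    lattice_shape = tuple(s + 1 for s in data.shape)
    flat = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), lattice_shape
    )
    unique_ids, elements = np.unique(flat, return_inverse=True)
    elements = elements.reshape(-1, 8).astype(np.int64)
    node_ijk = np.stack(np.unravel_index(unique_ids, lattice_shape), axis=1)
    spacing = np.asarray(mask.spacing)
    nodes = node_ijk * spacing + np.asarray(mask.origin)

    rho = density.data[data].astype(float)
    moduli = density_to_modulus(rho, law)
    return HexMesh(
        nodes=nodes.astype(float),
        elements=elements,
        element_density=rho,
        element_modulus=np.asarray(moduli, dtype=float),
        voxel_dims=mask.spacing,
    )


def _b_matrices(voxel_dims) -> tuple[np.ndarray, float]:
    """Strain-displacement matrices at the 8 Gauss points of the brick.

    Returns ``B`` of shape (8, 6, 24) in Voigt order
    (xx, yy, zz, xy, yz, zx) with engineering shear, and the Gauss-point
    integration weight (volume / 8).
    """
    a, b, c = voxel_dims
    if min(a, b, c) <= 0:
        raise ValueError(f"degenerate voxel dims {voxel_dims}")
    # natural coordinates of corners in [-1, 1]
    xi_n = 2.0 * _CORNERS - 1.0  # (8, 3)
    gps = _GAUSS * xi_n  # Gauss points share the corner pattern
    B = np.zeros((8, 6, 24))
    inv_j = np.array([2.0 / a, 2.0 / b, 2.0 / c])
    for g, (gx, gy, gz) in enumerate(gps):
        for node, (sx, sy, sz) in enumerate(xi_n):
            # dN/dxi of N = (1+sx*xi)(1+sy*eta)(1+sz*zeta)/8
            dn = np.array([
                sx * (1 + sy * gy) * (1 + sz * gz),
                (1 + sx * gx) * sy * (1 + sz * gz),
                (1 + sx * gx) * (1 + sy * gy) * sz,
            ]) / 8.0
            dndx = dn * inv_j
            cdof = 3 * node
            B[g, 0, cdof + 0] = dndx[0]
            B[g, 1, cdof + 1] = dndx[1]
            B[g, 2, cdof + 2] = dndx[2]
            B[g, 3, cdof + 0] = dndx[1]  # gamma_xy
            B[g, 3, cdof + 1] = dndx[0]
            B[g, 4, cdof + 1] = dndx[2]  # gamma_yz
            B[g, 4, cdof + 2] = dndx[1]
            B[g, 5, cdof + 0] = dndx[2]  # gamma_zx
            B[g, 5, cdof + 2] = dndx[0]
    weight = a * b * c / 8.0
    return B, weight


def _elastic_voigt(modulus: float, poisson: float) -> np.ndarray:
    lam = modulus * poisson / ((1 + poisson) * (1 - 2 * poisson))
    g = modulus / (2 * (1 + poisson))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * g
    C[np.arange(3, 6), np.arange(3, 6)] = g
    return C


def element_stiffness(modulus: float, poisson: float, voxel_dims) -> np.ndarray:
    """24x24 stiffness of one trilinear brick (2x2x2 Gauss quadrature)."""
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    B, w = _b_matrices(voxel_dims)
    C = _elastic_voigt(modulus, poisson)
    return w * np.einsum("gja,jk,gkb->ab", B, C, B)


def apply_axial_compression_bc(
    mesh: HexMesh, axis: int = 2, layer_mm: float | None = None,
    step_mm: float = 0.05, max_mm: float = 1.0, support: str = "clamped",
    top_mm: float | None = None, bottom_mm: float | None = None,
) -> BoundaryConditions:
    """Drive the top node layer axially, fully fix the bottom layer.

    ``layer_mm`` defaults to one voxel along ``axis``.  Driven nodes are
    those above ``top_mm - layer_mm`` along the loading axis, fixed nodes
    below ``bottom_mm + layer_mm``; the reference planes default to the
    mesh extremes.  Passing the planes of an unperturbed bone keeps the
    load path comparable across morphological variants: material a
    dilation adds beyond the reference top plane moves rigidly with the
    driven layer instead of being loaded in series.
    """
    if layer_mm is None:
        layer_mm = mesh.voxel_dims[axis]
    coords = mesh.nodes[:, axis]
    lo, hi = coords.min(), coords.max()
    hi_eff = hi if top_mm is None else min(top_mm, hi)
    lo_eff = lo if bottom_mm is None else max(bottom_mm, lo)
    # strictly within layer_mm of the reference planes: a one-voxel layer
    # selects only the end node plane; overlapping layers are rejected by
    # the BoundaryConditions disjointness invariant
    driven = np.flatnonzero(coords > hi_eff - layer_mm + 1e-9)
    fixed = np.flatnonzero(coords < lo_eff + layer_mm - 1e-9)
    return BoundaryConditions(fixed, driven, axis=axis, step_mm=step_mm,
                              max_mm=max_mm, support=support)


class _J2State:
    """Per-Gauss-point plastic strain (engineering Voigt), committed per step."""

    def __init__(self, n_elem: int):
        self.eps_p = np.zeros((n_elem, 8, 6))


def _return_mapping(eps, eps_p, C, G, K, sigma_y):
    """Vectorized radial return for J2 perfect plasticity.

    Parameters are per-(element, gp) arrays: ``eps``/``eps_p`` engineering
    Voigt strains (ne, 8, 6); ``sigma_y``, ``G``, ``K`` (ne,).  Returns
    stress (ne, 8, 6), updated plastic strain, consistent tangent
    (ne, 8, 6, 6), and a bool array marking plastic points.
    """
    ne = eps.shape[0]
    eps_e = eps - eps_p
    sigma_tr = np.einsum("eij,egj->egi", C, eps_e)
    p = sigma_tr[..., :3].mean(axis=-1)
    s = sigma_tr.copy()
    s[..., :3] -= p[..., None]
    # tensor norm: shear components count twice
    s_norm2 = (s[..., :3] ** 2).sum(-1) + 2.0 * (s[..., 3:] ** 2).sum(-1)
    s_norm = np.sqrt(np.maximum(s_norm2, 1e-300))
    q = np.sqrt(1.5) * s_norm
    sy = sigma_y[:, None]
    plastic = q > sy * (1.0 + 1e-12)

    stress = sigma_tr.copy()
    tangent = np.broadcast_to(C[:, None, :, :], (ne, 8, 6, 6)).copy()
    eps_p_new = eps_p.copy()
    if np.any(plastic):
        e_idx, g_idx = np.nonzero(plastic)
        Gp = G[e_idx]
        qp = q[plastic]
        syp = sy[:, 0][e_idx]
        sp = s[plastic]  # (np, 6) trial deviatoric stress
        scale = syp / qp
        stress_p = sp * scale[:, None]
        stress_p[:, :3] += p[plastic][:, None]
        stress[plastic] = stress_p
        # plastic strain increment: dgamma * sqrt(3/2) * n, engineering shear x2
        dgamma = (qp - syp) / (3.0 * Gp)
        flow = 1.5 * sp / qp[:, None]
        flow[:, 3:] *= 2.0
        eps_p_new[plastic] = eps_p[plastic] + dgamma[:, None] * flow
        # consistent tangent: K 1x1 + 2G theta (I_dev - n x n), theta = sy/q
        n_v = sp / s_norm[plastic][:, None]
        Kp = K[e_idx]
        theta = scale
        J = np.zeros((6, 6))
        J[:3, :3] = 1.0
        I_dev = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5]) - J / 3.0
        nn = np.einsum("pi,pj->pij", n_v, n_v)
        tangent[plastic] = (
            Kp[:, None, None] * J[None]
            + (2.0 * Gp * theta)[:, None, None] * (I_dev[None] - nn)
        )
    return stress, eps_p_new, tangent, plastic


def solve_nonlinear(
    mesh: HexMesh,
    bc: BoundaryConditions,
    law: MaterialLaw,
    tol: float = 1e-6,
    max_iter: int = 25,
) -> SolveResult:
    """Displacement-controlled quasi-static solve with J2 perfect plasticity.

    At each increment the driven nodes advance by ``bc.step_mm`` along the
    loading axis (compressive) and equilibrium is found by Newton iteration;
    the compressive reaction is the axial internal-force sum over the driven
    nodes.  Convergence requires the free-DOF residual norm to drop below
    ``tol`` times the external (reaction) force norm.
    """
    ndof = 3 * mesh.n_nodes
    B, w = _b_matrices(mesh.voxel_dims)
    E = mesh.element_modulus
    nu = law.poisson_ratio
    G = E / (2 * (1 + nu))
    Kbulk = E / (3 * (1 - 2 * nu))
    C_unit = _elastic_voigt(1.0, nu)
    C = E[:, None, None] * C_unit[None]
    sigma_y = E * law.yield_strain

    edof = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()

    if bc.support == "clamped":
        fixed_dofs = (3 * bc.fixed_nodes[:, None] + np.arange(3)[None, :]).ravel()
    else:  # roller: axial support plus 3-2-1 lateral constraints
        lat = [a for a in range(3) if a != bc.axis]
        fixed_dofs = [3 * bc.fixed_nodes + bc.axis]
        pts = mesh.nodes[bc.fixed_nodes][:, lat]
        a_loc = np.lexsort((pts[:, 1], pts[:, 0]))[0]
        node_a = bc.fixed_nodes[a_loc]
        fixed_dofs.append(np.array([3 * node_a + lat[0], 3 * node_a + lat[1]]))
        b_loc = int(np.argmax(np.abs(pts[:, 0] - pts[a_loc, 0])))
        node_b = bc.fixed_nodes[b_loc]
        fixed_dofs.append(np.array([3 * node_b + lat[1]]))
        fixed_dofs = np.concatenate(fixed_dofs)
    prescribed = np.unique(np.concatenate([fixed_dofs, 3 * bc.driven_nodes + bc.axis]))
    free = np.setdiff1d(np.arange(ndof), prescribed)
    driven_dofs = 3 * bc.driven_nodes + bc.axis

    def assemble(tangent):
        """Global tangent sliced to (free x free, free x driven) blocks."""
        Kel = w * np.einsum("gja,egjk,gkb->eab", B, tangent, B, optimize=True)
        Kg = coo_matrix((Kel.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsc()
        Kf = Kg[free]
        return Kf[:, free].tocsc(), Kf[:, driven_dofs].tocsc()

    def internal_forces(u):
        u_e = u[edof]  # (ne, 24)
        eps = np.einsum("gja,ea->egj", B, u_e)
        stress, eps_p_new, tangent, plastic = _return_mapping(
            eps, state.eps_p, C, G, Kbulk, sigma_y
        )
        f_el = w * np.einsum("gja,egj->ea", B, stress)
        f = np.zeros(ndof)
        np.add.at(f, edof.ravel(), f_el.ravel())
        return f, eps_p_new, tangent, plastic

    state = _J2State(mesh.n_elements)
    u = np.zeros(ndof)
    n_steps = int(round(bc.max_mm / bc.step_mm))
    displacements = np.zeros(n_steps)
    reactions = np.zeros(n_steps)

    # start from the elastic tangent; later factorizations are reused across
    # iterations and step boundaries (modified Newton) and refreshed with the
    # current consistent tangent only when the residual contraction stalls —
    # a factorization costs tens of cheap iterations on these meshes
    elastic_tangent = np.broadcast_to(C[:, None, :, :], (mesh.n_elements, 8, 6, 6))
    lu, K_fd = None, None

    for step in range(n_steps):
        target = bc.step_mm * (step + 1)
        if lu is None:
            K_ff, K_fd = assemble(elastic_tangent)
            lu = _factorize(K_ff, step)
        # incremental predictor: K_ff du_f = -K_fd du_d about the committed
        # state — applying the prescribed jump directly would put spurious
        # plastic strain concentrations at the driven layer
        du_d = np.full(driven_dofs.size, -bc.step_mm)
        u[driven_dofs] = -target
        u[free] -= lu.solve(K_fd @ du_d)
        converged = False
        prev_norm = np.inf
        for it in range(max_iter):
            f_int, eps_p_new, tangent, plastic = internal_forces(u)
            r_free = f_int[free]
            f_ext_norm = np.linalg.norm(f_int[prescribed])
            ref = max(f_ext_norm, 1e-8)
            r_norm = np.linalg.norm(r_free)
            if r_norm <= tol * ref:
                converged = True
                break
            # refresh the tangent when contraction stalls, and always in the
            # later iterations so the finish is quadratic
            if r_norm > 0.5 * prev_norm or it >= max_iter // 2:
                K_ff, K_fd = assemble(tangent if np.any(plastic) else elastic_tangent)
                lu = _factorize(K_ff, step)
            prev_norm = r_norm
            u[free] -= lu.solve(r_free)
        if not converged:
            raise RuntimeError(
                f"Newton failed to converge at step {step + 1} "
                f"(residual {np.linalg.norm(r_free):.3e}, tol {tol * ref:.3e})"
            )
        state.eps_p = eps_p_new  # commit plastic state
        displacements[step] = target
        reactions[step] = -float(f_int[driven_dofs].sum())  # compressive positive

    return SolveResult(displacements=displacements, reactions=reactions)


def _factorize(K_ff, step: int):
    try:
        # minimum-degree on A^T + A: much less fill than COLAMD on these
        # structurally symmetric voxel-lattice matrices
        return splu(K_ff, permc_spec="MMD_AT_PLUS_A")
    except RuntimeError as exc:  # singular factor: floating nodes
        raise RuntimeError(
            f"singular stiffness matrix at step {step + 1} (floating nodes?): {exc}"
        ) from exc


def failure_load(
    result: SolveResult,
    criterion: str = "femur_max_load",
    bone_height_mm: float | None = None,
) -> float:
    """Extract the failure load (N) from a load–displacement curve.

    ``femur_max_load``: the maximum reaction over the simulation.
    ``vertebra_height_reduction``: the reaction at the displacement equal to
    1.9% of ``bone_height_mm`` (linear interpolation between steps); an
    error if that displacement was never reached.
    """
    if result.reactions.size == 0:
        raise ValueError("empty load-displacement curve")
    if criterion == "femur_max_load":
        step = int(np.argmax(result.reactions))
        fl = float(result.reactions[step])
    elif criterion == "vertebra_height_reduction":
        if bone_height_mm is None or bone_height_mm <= 0:
            raise ValueError("the vertebral criterion needs a positive bone_height_mm")
        d_target = VERTEBRA_HEIGHT_STRAIN * bone_height_mm
        disp = result.displacements
        if disp[-1] < d_target - 1e-12:
            raise ValueError(
                "vertebral failure displacement "
                f"{d_target:.3f} mm not reached: increase max displacement"
            )
        step = int(np.searchsorted(disp, d_target - 1e-12))
        fl = float(np.interp(d_target, disp, result.reactions))
    else:
        raise ValueError(f"unknown failure criterion {criterion!r}")
    result.failure_load = fl
    result.failure_step = step
    result.criterion = criterion
    return fl
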