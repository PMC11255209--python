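"""Voxel hex meshing, element stiffness, and the nonlinear solver.

The solver is validated against closed-form uniaxial elasticity
(R = E A delta / L) and the perfectly-plastic limit load (R = sigma_y A)
on homogeneous columns under frictionless (roller) end conditions, where
the analytic solution is exact for trilinear bricks.
"""

import numpy as np
import pytest

import bonefail as bf
from bonefail.calibrate import MaterialLaw, vertebra_law
from bonefail.fem import (
    BoundaryConditions,
    apply_axial_compression_bc,
    build_hex_mesh,
    element_stiffness,
    failure_load,
    solve_nonlinear,
    SolveResult,
)
from conftest import column_mesh


class TestBuildHexMesh:
    def test_cube_lattice_counts(self):
        mask = bf.Mask(np.ones((2, 2, 2), np.uint8), (1, 1, 1))
        dens = bf.Volume(np.ones((2, 2, 2)), (1, 1, 1))
        mesh = build_hex_mesh(mask, dens, bf.femur_law())
        assert mesh.n_elements == 8
        assert mesh.n_nodes == 27

    def test_single_voxel(self):
        mask = bf.Mask(np.ones((1, 1, 1), np.uint8), (1, 1, 1))
        dens = bf.Volume(np.ones((1, 1, 1)), (1, 1, 1))
        mesh = build_hex_mesh(mask, dens, bf.femur_law())
        assert mesh.n_elements == 1 and mesh.n_nodes == 8

    def test_element_density_is_voxel_density(self, femur_phantom, unit_calibration):
        vol, mask = femur_phantom
        dens = bf.hu_to_density(vol, unit_calibration)
        mesh = build_hex_mesh(mask, dens, bf.femur_law())
        np.testing.assert_array_equal(
            mesh.element_density, dens.data[mask.data.astype(bool)]
        )

    def test_empty_mask_rejected(self):
        mask = bf.Mask(np.zeros((3, 3, 3), np.uint8), (1, 1, 1))
        dens = bf.Volume(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            build_hex_mesh(mask, dens, bf.femur_law())

    def test_disconnected_mask_keeps_largest(self):
        data = np.zeros((9, 3, 3), np.uint8)
        data[0:4] = 1
        data[6:8] = 1
        mask = bf.Mask(data, (1, 1, 1))
        dens = bf.Volume(np.ones((9, 3, 3)), (1, 1, 1))
        with pytest.warns(UserWarning, match="connected components"):
            mesh = build_hex_mesh(mask, dens, bf.femur_law())
        assert mesh.n_elements == 4 * 9

    def test_vtk_export_is_readable_text(self, tmp_path):
        mask = bf.Mask(np.ones((2, 2, 2), np.uint8), (1, 1, 1))
        dens = bf.Volume(np.ones((2, 2, 2)), (1, 1, 1))
        mesh = build_hex_mesh(mask, dens, bf.femur_law())
        path = tmp_path / "mesh.vtk"
        mesh.save_vtk(path)
        text = path.read_text()
        assert "UNSTRUCTURED_GRID" in text and "POINTS 27" in text


class TestElementStiffness:
    def test_symmetric(self):
        K = element_stiffness(12_000.0, 0.3, (0.78, 0.78, 0.67))
        assert np.max(np.abs(K - K.T)) < 1e-10 * np.max(np.abs(K))

    def test_six_rigid_body_modes(self):
        K = element_stiffness(10_000.0, 0.3, (1.0, 1.0, 1.0))
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-8 * w.max()) == 6
        assert np.all(w > -1e-8 * w.max())  # positive semi-definite

    def test_linear_in_modulus(self):
        K1 = element_stiffness(5_000.0, 0.25, (1.0, 1.2, 0.8))
        K2 = element_stiffness(10_000.0, 0.25, (1.0, 1.2, 0.8))
        np.testing.assert_allclose(K2, 2.0 * K1, rtol=1e-12)

    def test_degenerate_dims_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            element_stiffness(1000.0, 0.3, (1.0, 0.0, 1.0))


class TestBoundaryConditions:
    def test_column_layer_counts(self):
        mesh, _ = column_mesh(1, 1, 10)
        bc = apply_axial_compression_bc(mesh, layer_mm=1.0)
        assert bc.driven_nodes.size == 4
        assert bc.fixed_nodes.size == 4

    def test_full_span_layer_rejected(self):
        mesh, _ = column_mesh(1, 1, 10)
        with pytest.raises(ValueError, match="disjoint"):
            apply_axial_compression_bc(mesh, layer_mm=11.0)

    def test_sets_disjoint(self, femur_phantom, unit_calibration):
        vol, mask = femur_phantom
        dens = bf.hu_to_density(vol, unit_calibration)
        mesh = build_hex_mesh(mask, dens, bf.femur_law())
        bc = apply_axial_compression_bc(mesh, layer_mm=2.0)
        assert np.intersect1d(bc.fixed_nodes, bc.driven_nodes).size == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="step_mm"):
            BoundaryConditions(np.array([0]), np.array([1]), step_mm=0.0)
        with pytest.raises(ValueError, match="disjoint"):
            BoundaryConditions(np.array([0, 1]), np.array([1, 2]))


class TestSolveNonlinear:
    def test_single_element_elastic_reaction(self):
        # E A delta / L = 10000 * 1 * 0.001 / 1 = 10 N
        mesh, law = column_mesh(1, 1, 1, modulus=10_000.0, poisson=0.0)
        bc = apply_axial_compression_bc(mesh, step_mm=0.001, max_mm=0.001)
        res = solve_nonlinear(mesh, bc, law)
        assert res.reactions[-1] == pytest.approx(10.0, rel=1e-9)

    def test_single_element_plastic_plateau(self):
        # driven to 3% strain with 1.5% yield: plateau at sigma_y A = 150 N
        mesh, law = column_mesh(1, 1, 1, modulus=10_000.0, poisson=0.0)
        bc = apply_axial_compression_bc(mesh, step_mm=0.003, max_mm=0.03,
                                        support="roller")
        res = solve_nonlinear(mesh, bc, law)
        assert res.reactions[-1] == pytest.approx(150.0, rel=1e-6)
        assert res.reactions[4] == pytest.approx(150.0, rel=1e-6)  # 1.5% strain

    @pytest.mark.parametrize("shape", [(1, 1, 1), (2, 2, 2), (5, 5, 5)])
    def test_homogeneous_column_oracles(self, shape):
        nx, ny, nz = shape
        mesh, law = column_mesh(nx, ny, nz, modulus=8_000.0, poisson=0.3)
        area, height = nx * ny, nz
        bc = apply_axial_compression_bc(
            mesh, step_mm=0.006 * height, max_mm=0.03 * height, support="roller"
        )
        res = solve_nonlinear(mesh, bc, law)
        elastic = 8_000.0 * area * res.displacements[0] / height
        assert res.reactions[0] == pytest.approx(elastic, rel=0.01)
        assert res.reactions[-1] == pytest.approx(8_000.0 * 0.015 * area, rel=0.02)

    def test_near_zero_displacement_gives_near_zero_reactions(self):
        mesh, law = column_mesh(2, 2, 4)
        bc = apply_axial_compression_bc(mesh, step_mm=1e-12, max_mm=3e-12)
        res = solve_nonlinear(mesh, bc, law)
        assert np.all(np.abs(res.reactions) < 1e-6)

    def test_mesh_refinement_consistency(self):
        """Halving the voxel size leaves the elastic reaction unchanged."""
        coarse, law = column_mesh(2, 2, 8, spacing=1.0)
        fine, _ = column_mesh(4, 4, 16, spacing=0.5)
        results = []
        for mesh in (coarse, fine):
            bc = apply_axial_compression_bc(
                mesh, layer_mm=mesh.voxel_dims[2], step_mm=0.008, max_mm=0.008,
                support="roller",
            )
            results.append(solve_nonlinear(mesh, bc, law).reactions[-1])
        assert results[1] == pytest.approx(results[0], rel=0.01)

    def test_external_work_nonnegative_and_nondecreasing(self):
        mesh, law = column_mesh(2, 2, 6)
        bc = apply_axial_compression_bc(mesh, step_mm=0.02, max_mm=0.2)
        res = solve_nonlinear(mesh, bc, law)
        increments = np.diff(np.concatenate([[0.0], res.displacements]))
        work = np.cumsum(res.reactions * increments)
        assert np.all(work >= 0)
        assert np.all(np.diff(work) >= 0)


class TestFailureLoad:
    def test_femur_max_of_curve(self):
        res = SolveResult(np.array([0.1, 0.2, 0.3]), np.array([1.0, 2.0, 3.0]))
        assert failure_load(res, "femur_max_load") == 3.0
        res = SolveResult(np.array([0.1, 0.2, 0.3]), np.array([1.0, 5.0, 4.0]))
        assert failure_load(res, "femur_max_load") == 5.0
        assert res.failure_step == 1

    def test_vertebra_height_reduction_on_column(self):
        """Homogeneous 30 mm column: FL read at 0.57 mm (1.9% of height) and
        equal to the closed-form plateau there."""
        mesh, _ = column_mesh(3, 3, 30, modulus=611.3, poisson=0.0)
        law = vertebra_law(poisson_ratio=0.0)
        bc = apply_axial_compression_bc(mesh, step_mm=0.03, max_mm=0.63, support="roller")
        res = solve_nonlinear(mesh, bc, law)
        fl = failure_load(res, "vertebra_height_reduction", bone_height_mm=30.0)
        assert res.displacements[res.failure_step] == pytest.approx(0.57, abs=0.03)
        # past yield (0.45 mm), so the plateau value applies: sigma_y * A
        assert fl == pytest.approx(611.3 * 0.015 * 9, rel=0.02)

    def test_vertebra_criterion_unreachable(self):
        res = SolveResult(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="increase max displacement"):
            failure_load(res, "vertebra_height_reduction", bone_height_mm=30.0)

    def test_unknown_criterion_rejected(self):
        res = SolveResult(np.array([0.1]), np.array([1.0]))
        with pytest.raises(ValueError, match="criterion"):
            failure_load(res, "maximum_entropy")
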