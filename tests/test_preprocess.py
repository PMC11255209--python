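"""Pre-processing: resampling geometry, split/flip, registration recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import bonefail as bf
from bonefail.preprocess import (
    flip_lr,
    normalize_intensity,
    register_affine,
    resample,
    split_and_flip,
)


@pytest.fixture(scope="module")
def reg_phantom():
    """A larger noiseless femur used as the registration target."""
    spec = bf.PhantomSpec(
        grid_shape=(32, 32, 44), spacing=(1.0, 1.0, 1.0), bone_kind="femur",
        outer_radius_mm=7.0, cortical_thickness_mm=2.0, height_mm=32.0,
    )
    vol, _ = bf.generate_bone_phantom(spec)
    return vol


class TestResample:
    def test_halving_spacing_doubles_shape(self):
        spec = bf.PhantomSpec(
            grid_shape=(24, 24, 36), spacing=(1.56, 1.56, 1.34), bone_kind="femur",
            outer_radius_mm=6.0, cortical_thickness_mm=2.0, height_mm=30.0,
        )
        vol, mask = bf.generate_bone_phantom(spec)
        out = resample(vol, (0.78, 0.78, 0.67), "linear")
        assert out.shape == (48, 48, 72)
        assert out.spacing == (0.78, 0.78, 0.67)
        # world extent preserved to within one voxel
        for a in range(3):
            assert abs(out.extent_mm()[a] - vol.extent_mm()[a]) <= max(out.spacing[a],
                                                                       vol.spacing[a])

    def test_identity_target_returns_input(self, femur_phantom):
        vol, _ = femur_phantom
        out = resample(vol, vol.spacing, "linear")
        np.testing.assert_array_equal(out.data, vol.data)

    def test_constant_volume_stays_constant(self):
        vol = bf.Volume(np.full((10, 12, 8), 37.0), (1.0, 1.3, 0.9))
        out = resample(vol, (0.7, 0.7, 0.7), "linear")
        np.testing.assert_allclose(out.data, 37.0, rtol=1e-6)

    def test_mask_resampling_stays_binary_and_idempotent(self, femur_phantom):
        _, mask = femur_phantom
        out = resample(mask, (0.78, 0.78, 0.67))
        assert set(np.unique(out.data)) <= {0, 1}
        again = resample(out, (0.78, 0.78, 0.67))
        assert np.abs(again.data.astype(float) - out.data.astype(float)).max() < 1e-6

    def test_bad_spacing_rejected(self, femur_phantom):
        vol, _ = femur_phantom
        with pytest.raises(ValueError, match="positive"):
            resample(vol, (0.0, 1.0, 1.0))


class TestNormalize:
    def test_zscore_moments(self, femur_phantom):
        vol, _ = femur_phantom
        out = normalize_intensity(vol)
        assert abs(float(out.data.mean())) < 1e-5
        assert abs(float(out.data.std()) - 1.0) < 1e-5

    def test_affine_intensity_invariance(self, femur_phantom):
        vol, _ = femur_phantom
        scaled = bf.Volume(2.5 * vol.data + 100.0, vol.spacing)
        np.testing.assert_allclose(
            normalize_intensity(scaled).data, normalize_intensity(vol).data, atol=1e-4
        )

    def test_gaussian_volume_normalizes_to_standard_moments(self):
        rng = np.random.default_rng(0)
        vol = bf.Volume(rng.normal(500.0, 100.0, size=(20, 20, 20)), (1, 1, 1))
        out = normalize_intensity(vol)
        assert abs(float(out.data.mean())) < 1e-6
        assert abs(float(out.data.std()) - 1.0) < 1e-6

    def test_zero_variance_rejected(self):
        vol = bf.Volume(np.full((5, 5, 5), 3.0), (1, 1, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            normalize_intensity(vol)


class TestSplitAndFlip:
    def test_mirror_identical_specs_give_identical_halves(self, femur_spec):
        hip, _, _ = bf.generate_hip_volume(femur_spec, femur_spec, gap_mm=20.0)
        left, right = split_and_flip(hip)
        np.testing.assert_array_equal(left.data, right.data)

    def test_each_half_contains_one_component(self, femur_spec):
        hip, _, _ = bf.generate_hip_volume(femur_spec, femur_spec, gap_mm=20.0)
        for half in split_and_flip(hip):
            _, n = ndimage.label(half.data >= 170.0)
            assert n == 1

    def test_bone_voxel_conservation(self, femur_spec):
        hip, lmask, rmask = bf.generate_hip_volume(femur_spec, femur_spec, gap_mm=20.0)
        halves = split_and_flip(hip)
        total = sum(int(np.count_nonzero(h.data >= 170.0)) for h in halves)
        assert total == int(np.count_nonzero(hip.data >= 170.0))

    def test_flip_is_involution(self, femur_phantom):
        vol, _ = femur_phantom
        np.testing.assert_array_equal(flip_lr(flip_lr(vol)).data, vol.data)

    def test_wrong_component_count_reported(self, femur_phantom):
        vol, _ = femur_phantom  # a single bone
        with pytest.raises(ValueError, match="found 1"):
            split_and_flip(vol)


class TestRegisterAffine:
    def test_translation_recovery(self, reg_phantom):
        shift = (5.0, 0.0, 0.0)
        moved = bf.Volume(
            ndimage.shift(reg_phantom.data, shift, order=1, mode="nearest"),
            reg_phantom.spacing,
        )
        transform, resampled = register_affine(moved, reg_phantom)
        centre = (np.array(reg_phantom.shape) - 1) / 2.0 * np.array(reg_phantom.spacing)
        recovered = transform.displacement_at(centre)
        np.testing.assert_allclose(recovered, [-5.0, 0.0, 0.0], atol=0.5)

    def test_self_registration_is_identity(self, reg_phantom):
        transform, _ = register_affine(reg_phantom, reg_phantom)
        centre = (np.array(reg_phantom.shape) - 1) / 2.0
        assert np.abs(transform.displacement_at(centre)).max() < 0.5
        np.testing.assert_allclose(transform.matrix, np.eye(3), atol=0.05)

    def test_isotropic_scaling_recovery(self, reg_phantom):
        zoom = 1.10
        centre = (np.array(reg_phantom.shape) - 1) / 2.0
        grids = np.meshgrid(*[np.arange(n) for n in reg_phantom.shape], indexing="ij")
        pts = [(g - c) / zoom + c for g, c in zip(grids, centre)]
        moved = bf.Volume(
            ndimage.map_coordinates(reg_phantom.data, np.stack(pts), order=1,
                                    mode="nearest"),
            reg_phantom.spacing,
        )
        transform, _ = register_affine(moved, reg_phantom)
        det = float(np.linalg.det(transform.matrix))
        assert abs(det - 1.0 / zoom**3) / (1.0 / zoom**3) < 0.05

    def test_random_small_affines_recovered(self, reg_phantom):
        """Parameter-recovery suite: random translations up to 10 mm and
        scales in [0.9, 1.1]; mean translation error below one voxel."""
        rng = np.random.default_rng(11)
        errors = []
        for _ in range(4):
            t = rng.uniform(-10, 10, size=3) * [1, 1, 0.5]
            s = rng.uniform(0.9, 1.1)
            centre = (np.array(reg_phantom.shape) - 1) / 2.0
            grids = np.meshgrid(*[np.arange(n) for n in reg_phantom.shape], indexing="ij")
            pts = [(g - c) / s + c - tt for g, c, tt in zip(grids, centre, t)]
            moved = bf.Volume(
                ndimage.map_coordinates(reg_phantom.data, np.stack(pts), order=1,
                                        mode="nearest"),
                reg_phantom.spacing,
            )
            transform, _ = register_affine(moved, reg_phantom)
            centre_mm = centre * np.array(reg_phantom.spacing)
            # the construction displaces the image centre by exactly -t (mm)
            recovered = transform.displacement_at(centre_mm)
            errors.append(np.linalg.norm(recovered + t))
        assert np.mean(errors) < 1.0

    def test_constant_volume_rejected(self, reg_phantom):
        flat = bf.Volume(np.zeros_like(reg_phantom.data), reg_phantom.spacing)
        with pytest.raises(ValueError, match="constant"):
            register_affine(flat, reg_phantom)
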