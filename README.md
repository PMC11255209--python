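# bonefail

Finite-element failure-load estimation for femurs and vertebrae from CT,
with a built-in study of how sensitive the predicted failure load is to
segmentation errors.

Pathologic fractures from osteolytic metastases are hard to anticipate from
images alone; subject-specific finite-element (FE) models built from
quantitative CT give a mechanistic failure-load estimate, but they inherit
every error of the upstream bone segmentation. `bonefail` implements the
full chain — CT pre-processing, segmentation post-processing, QCT density
calibration, voxel-based hexahedral FE failure-load computation — plus the
morphological-perturbation experiment that quantifies how erosion or
dilation of a segmentation propagates into the failure load. Everything is
exercised on synthetic bone phantoms with known geometry and intensities,
so the whole pipeline is testable without clinical data; externally
produced NIfTI masks (e.g. from a trained network) can be dropped in at any
point.

## Model

CT intensities (HU) are mapped to bone-equivalent density
ρ<sub>QCT</sub> (g/cm³) by a least-squares line fitted on calibration-rod
regions of known density. Density maps to Young's modulus:

* femur: E(MPa) = 14900 · ρ<sub>QCT</sub><sup>1.86</sup>
* vertebra: E(MPa) = 3230 · ρ<sub>QCT</sub> − 34.7

Each segmented voxel becomes one 8-node hexahedral element carrying its
voxel's density and modulus. The constitutive model is small-strain linear
elastic–perfectly plastic (von Mises), with per-element yield stress
σ<sub>y</sub> = E · ε<sub>y</sub> and yield strain ε<sub>y</sub> = 1.5%.
Quasi-static axial compression is displacement-controlled: the top node
layer advances incrementally while the bottom layer is fixed, and each
increment is equilibrated by Newton iteration with a consistent tangent and
a direct sparse solver. The failure load is

* femur: the maximum reaction over the loading history;
* vertebra: the reaction when the applied displacement reaches 1.9% of the
  vertebral height.

The sensitivity study perturbs an automatic segmentation by binary erosion
or dilation (1 or 2 one-voxel layers, 6-connected), reruns the pipeline for
each variant, and compares Dice score (DSC), Hausdorff distance (HD, mm)
and failure load against the reference segmentation; a Friedman test with
Dunn post-hoc comparisons assesses differences across variants over a
cohort of bones.

## Worked example

```python
import bonefail as bf

spec = bf.PhantomSpec(grid_shape=(18, 18, 28), spacing=(1, 1, 1),
                      bone_kind="femur", outer_radius_mm=4.0,
                      cortical_thickness_mm=1.5, height_mm=20.0,
                      noise_sd=5.0, seed=1)
vol, truth = bf.generate_bone_phantom(spec)
auto = bf.segment_bone(vol, hu_threshold=170.0)

# calibration rods of known density in the field of view
layout = bf.default_rod_layout(spec.grid_shape, spec.spacing, radius_mm=1.5)
vol = bf.embed_rods(vol, layout, bone_mask=truth)

config = bf.PipelineConfig(bone_kind="femur", rod_layout=layout,
                           layer_mm=2.0, step_mm=0.12, max_mm=0.48)
report = bf.run_sensitivity(vol, auto, truth, config)
print(report.table.round(3))
print("reference failure load:", round(report.reference_failure_load_N, 1), "N")
```

prints

```
           dsc  hd_mm  failure_load_N  abs_diff_N  pct_diff
erode2   0.412  2.828         288.161    9916.535    97.176
erode1   0.721  1.414        5030.778    5173.918    50.701
none     1.000  0.000       10204.697       0.000     0.000
dilate1  0.784  1.000       10229.272      24.575     0.241
dilate2  0.620  2.000       10271.072      66.375     0.650
reference failure load: 10204.7 N
```

Reading the table: the unperturbed automatic mask reproduces the reference
failure load almost exactly (0.003%), dilation adds only low-stiffness
soft-tissue voxels and shifts the load slightly upward, while erosion
removes load-bearing cortical bone and collapses the failure load — eroding
two layers costs 97% of the load here. DSC is maximal for the unperturbed
mask and decays toward both two-iteration extremes. Under-segmentation is
far more damaging than over-segmentation of the same nominal magnitude.

## Command line

```bash
bonefail phantom --out run/ --kind femur --seed 1 --rods
bonefail segment run/volume.nii.gz run/auto.nii.gz --threshold 170
bonefail perturb run/auto.nii.gz run/eroded.nii.gz --op erode --iters 2
bonefail metrics run/auto.nii.gz run/mask.nii.gz
bonefail simulate run/volume.nii.gz run/auto.nii.gz --bone femur --slope 0.001
bonefail sensitivity run/volume.nii.gz run/auto.nii.gz run/mask.nii.gz --slope 0.001
```

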