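# Methods

## Overview

`bonefail` estimates the compressive failure load of a bone from a CT
volume and a binary segmentation, and measures how segmentation errors
propagate into that estimate. The chain is: density calibration from
phantom rods → per-voxel Young's modulus → voxel-based hexahedral FE mesh
→ displacement-controlled nonlinear compression → failure-load extraction.
A synthetic-phantom generator supplies inputs with exactly known geometry
and intensities so every stage can be validated against analytic oracles.

## Density calibration

Rod regions of known equivalent density (g/cm³, the K₂HPO₄ phantom
convention) are sampled in the image; an ordinary-least-squares line maps
HU to ρ<sub>QCT</sub>. A non-positive fitted slope is rejected as an
inconsistent phantom. Calibrated densities below zero (air, marrow,
soft tissue after noise) are clamped to 0. The default synthetic layout
uses five rods spanning 0–800 HU and 0–0.8 g/cm³, i.e. slope
0.001 (g/cm³)/HU through the origin.

## Material laws

* Femur (power law): E(MPa) = 14900 · ρ<sup>1.86</sup>
* Vertebra (linear law): E(MPa) = 3230 · ρ − 34.7

Both are floored at `e_floor` (default 0.01 MPa) so that zero-density
voxels swept into a mask (over-segmented soft tissue, marrow) produce
near-zero but non-singular stiffness; the linear law would otherwise go
negative below ρ ≈ 0.0107 g/cm³. Poisson's ratio defaults to 0.3, the
standard choice in bone FE. Plasticity is elastic–perfectly plastic
(von Mises) with yield stress σ<sub>y</sub> = E · ε<sub>y</sub> and yield
strain ε<sub>y</sub> = 1.5% for both bone types; the femoral law is a
configurable stand-in of the same family, since the published femoral
models use a nonlinear constitutive curve whose parameters are not part
of this package.

## Finite elements and solver

Every in-mask voxel is one trilinear 8-node brick (2×2×2 Gauss
quadrature) sharing nodes with its face neighbours; element size equals
voxel size, so anisotropic spacing yields anisotropic bricks. Units are
mm / MPa / N. A disconnected mask is reduced to its largest 6-connected
component (with a warning) so eroded masks that fragment still solve.

Loading is displacement-controlled axial compression. Driven nodes lie
within `layer_mm` (default one voxel) of the top reference plane along the
loading axis, fixed nodes within `layer_mm` of the bottom plane. Two
support modes exist:

* `clamped` (default): fixed nodes constrained on all axes — the bone
  simulation condition;
* `roller`: fixed nodes constrained axially with minimal 3-2-1 lateral
  constraints — the frictionless-platen idealization under which a
  homogeneous prismatic column admits the exact closed-form solution
  (R = E·A·δ/L elastically, R = σ<sub>y</sub>·A on the plastic plateau),
  used by the validation oracles.

In sensitivity runs the reference planes are anchored to the unperturbed
bone's axial extent, so material a dilation adds beyond the top plane
moves rigidly with the driven layer instead of being loaded in series; a
soft voxel cap would otherwise dominate the load path and make variants
incomparable.

Each increment (default 0.1% of bone height; total travel default 2.5% of
height) is equilibrated by Newton iteration on the free degrees of
freedom, with a J2 radial-return mapping per Gauss point and the
consistent elastoplastic tangent. The increment is initialized by a linear
predictor (K<sub>ff</sub>Δu<sub>f</sub> = −K<sub>fd</sub>Δu<sub>d</sub>)
about the last converged state; applying the prescribed jump directly
would create spurious plastic strain at the driven layer. Linear systems
use SuperLU with minimum-degree ordering on AᵀT+A; factorizations are
reused across iterations and steps (modified Newton) and refreshed with
the current consistent tangent when the residual contraction per iteration
falls below 2×, and always in the later iterations of a step. Convergence
requires the free-DOF residual norm below 10⁻⁶ of the reaction-force norm,
within 25 iterations.

Failure load: femur — maximum reaction over the history (with perfect
plasticity and monotone loading this is the plateau value); vertebra — the
reaction, linearly interpolated between steps, where applied displacement
reaches 1.9% of the vertebral height. Compressive loads are reported
positive.

## Segmentation, perturbation and metrics

The built-in segmenter is a classical stand-in: threshold at a configurable
HU (default 170, midway between soft tissue and trabecular bone in the
phantoms), morphological hole filling, and removal of components below a
voxel count. Any externally produced NIfTI mask can replace it.
Post-processing is an opening (erosion + dilation) followed by island
removal. The perturbation operator applies 0, 1 or 2 iterations of binary
erosion or dilation with the 6-connected cross (one voxel layer per
iteration, acting in voxel space; 26-connectivity available). The cross
makes "one pixel" literal along each axis; which kernel real studies used
is generally unstated, so both are offered.

DSC is 2|A∩B|/(|A|+|B|) (two empty masks define 1). The Hausdorff distance
is computed between boundary-voxel sets in world millimetres — equivalent
to the filled-volume HD for the maximum and much cheaper; the 95th
percentile variant is available. The Friedman test uses per-row midranks
with the tie-corrected χ² statistic on k−1 degrees of freedom (an exact
permutation p-value is available for small matrices); it is implemented
in-package because the pipeline also needs the k = 2 case, and is
cross-checked against scipy for k ≥ 3 in the test suite. Dunn's post-hoc
compares each condition against the reference via rank-sum z-statistics,
Bonferroni-adjusted over the k−1 reference comparisons only — matching a
reporting style where only comparisons with the manual segmentation are
shown; the exact correction used in published analyses is typically
unstated.

## Synthetic phantoms

Geometry is analytic — a femur-like tube (cortical shell, trabecular
interior, fully enclosed marrow canal, hemispherical head cap) or a
vertebra-like cylinder (shell + core) — and voxel membership is a
voxel-centre-in-solid test, so voxel counts and class means are exact
oracles. Default HU means: cortical 1200, trabecular 300, marrow 0, soft
tissue 40; default spacing 0.78 × 0.78 × 0.67 mm (the anisotropic grid the
pre-processing standardizes on); noise is additive white Gaussian with
configurable SD. Osteolytic lesions are spheres of replaced intensity
strictly inside the bone; they change intensities, never the ground-truth
mask. Hip volumes place two mirrored femurs with a configurable
soft-tissue gap. Identical spec + seed reproduces bit-identical output.

What the phantoms do **not** emulate: trabecular microarchitecture,
partial-volume effects at tissue boundaries, beam hardening, scanner
reconstruction kernels, correlated noise, or realistic femoral anatomy
(neck angle, curvature). Passing tests therefore demonstrate correctness
of the computational chain and the direction/ordering of segmentation
effects, not clinical accuracy on real scans.

## Pre-processing

Resampling maps cell-centred grids with coincident outer edges; the output
shape per axis is round(extent/target), images use trilinear and masks
nearest-neighbour interpolation. Bilateral volumes are split at the
mid-gap plane between the two bone components' x-extents and the left half
is mirrored about x. Registration (SimpleITK) minimizes mean-squared
intensity difference with a 3-level multi-resolution pyramid and
regular-step gradient descent (200 iterations per level); if optimization
fails to improve on identity, the identity transform is returned with a
flag. All volumes are registered to a chosen reference (in practice the
first right femur — one admissible convention; nothing downstream depends
on it). Normalization is a per-volume z-score, the standard network-input
choice that needs no population statistics. Because an affine fit can
trade translation against its linear part, translation recovery is
assessed by the transform's displacement of the volume centre.

## Test and validation problem sizes

Validation columns range from 1 to 1000 elements. The
segmentation-sensitivity experiment uses ten femur phantoms with
randomized geometry (outer radius 3.6–4.6 mm, cortical thickness
1.3–1.8 mm, height 18–22 mm on a 1 mm grid, ≈ 700–1300 elements,
noise SD 5 HU), loaded in 0.12 mm steps to 0.48 mm — past yield, where the
failure-load ordering across erosion/dilation variants is meaningful.
These sizes are the package's chosen study conditions for desk-scale
validation; the pipeline itself has no intrinsic size limit beyond memory
and the direct solver's fill-in.

## Known limitations

* Small-strain kinematics; no geometric nonlinearity, contact or fatigue.
* Perfect plasticity for both bone types; no post-yield softening and no
  damage, so the femoral "maximum load" is a plateau rather than a peak.
* Vertebrae reuse the voxel-hexahedral mesher (a deliberate
  simplification; at ≈ 1 mm voxels the element volume matches the ≈ 1 mm³
  elements used in published vertebral models, but quadratic tetrahedra
  are not reproduced).
* Lesions inherit the density→modulus law; no metastasis-specific material
  properties.
* The threshold segmenter is a stand-in for learned segmentation and is
  only meaningful on phantom-like intensity distributions.
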