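"""End-to-end orchestration: CT + mask -> failure load, and the
segmentation-sensitivity experiment.

``run_failure_pipeline`` chains density calibration, voxel-hex meshing,
boundary conditions, the nonlinear solve and the failure criterion.
``run_sensitivity`` repeats the run for a reference mask and the five
morphological variants of an automatic mask (erode x2, erode x1, none,
dilate x1, dilate x2), recording overlap metrics and failure-load
differences against the reference.  ``batch_report`` aggregates several
bones into mean +/- SD summaries with a Friedman test across conditions
and Dunn post-hoc comparisons against the reference.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .calibrate import (
    DensityCalibration,
    MaterialLaw,
    femur_law,
    fit_hu_density,
    hu_to_density,
    vertebra_law,
)
from .core import Mask, Volume
from .fem import (
    SolveResult,
    apply_axial_compression_bc,
    build_hex_mesh,
    failure_load,
    solve_nonlinear,
)
from .phantom import RodLayout, measure_rod_means
from .preprocess import resample
from .segment import VARIANT_GRID, PerturbationSpec, perturb_mask

__all__ = [
    "PipelineConfig",
    "SensitivityReport",
    "run_failure_pipeline",
    "run_sensitivity",
    "batch_report",
]

VARIANT_LABELS = tuple(v.label for v in VARIANT_GRID)  # erode2 ... dilate2


@dataclass
class PipelineConfig:
    """Everything one failure-load run needs besides the image and mask."""

    bone_kind: str = "femur"  # selects material law and failure criterion
    target_spacing: tuple[float, float, float] | None = None  # None -> no resampling
    calibration: DensityCalibration | None = None
    rod_layout: RodLayout | None = None  # used to fit calibration from the image
    material_law: MaterialLaw | None = None  # None -> default law for bone_kind
    axis: int = 2
    layer_mm: float | None = None  # BC layer thickness; None -> one voxel
    bc_top_mm: float | None = None  # driven plane; None -> mesh top
    bc_bottom_mm: float | None = None  # fixed plane; None -> mesh bottom
    bone_height_mm: float | None = None  # None -> derived from the mask extent
    step_mm: float | None = None  # None -> 0.1% of bone height
    max_mm: float | None = None  # None -> 2.5% of bone height
    support: str = "clamped"  # "roller" = frictionless platens (column oracles)
    newton_tol: float = 1e-6
    newton_max_iter: int = 25
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bone_kind not in ("femur", "vertebra"):
            raise ValueError(f"unknown bone_kind {self.bone_kind!r}")

    def law(self) -> MaterialLaw:
        if self.material_law is not None:
            return self.material_law
        return femur_law() if self.bone_kind == "femur" else vertebra_law()

    @property
    def criterion(self) -> str:
        return "femur_max_load" if self.bone_kind == "femur" else "vertebra_height_reduction"


@dataclass
class SensitivityReport:
    """Per-variant metrics and failure loads for one bone.

    ``table`` is indexed by variant label (erode2, erode1, none, dilate1,
    dilate2) with columns ``dsc``, ``hd_mm``, ``failure_load_N``,
    ``abs_diff_N`` and ``pct_diff`` (percent difference normalized by the
    reference-mask failure load).  Failed variants carry NaN rows.
    """

    reference_failure_load_N: float
    table: pd.DataFrame

    def save_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="variant")


def _stage(name):
    """Decorator-ish context: re-raise stage errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def _resolve_calibration(ct: Volume, config: PipelineConfig) -> DensityCalibration:
    if config.calibration is not None:
        return config.calibration
    if config.rod_layout is not None:
        hu = measure_rod_means(ct, config.rod_layout)
        return fit_hu_density(hu, config.rod_layout.densities)
    raise ValueError("need calibration rods in the image or a DensityCalibration")


def _bone_height_mm(mask: Mask, axis: int) -> float:
    occupied = np.flatnonzero(mask.data.any(axis=tuple(a for a in range(3) if a != axis)))
    return float((occupied[-1] - occupied[0] + 1) * mask.spacing[axis])


def run_failure_pipeline(
    ct: Volume,
    mask: Mask,
    config: PipelineConfig,
    reference_mask: Mask | None = None,
) -> tuple[SolveResult, "_metrics.MetricReport | None"]:
    """Calibrate, mesh, and solve one bone; returns the load–displacement
    result (with the failure load filled in) and, when a reference mask is
    supplied, the DSC/HD agreement of ``mask`` against it."""
    with _stage("calibrate"):
        calib = _resolve_calibration(ct, config)
    if config.target_spacing is not None:
        with _stage("resample"):
            ct = resample(ct, config.target_spacing, "linear")
            mask = resample(mask, config.target_spacing)
            if reference_mask is not None:
                reference_mask = resample(reference_mask, config.target_spacing)
    with _stage("hu_to_density"):
        density = hu_to_density(ct, calib)
    law = config.law()
    with _stage("mesh"):
        mesh = build_hex_mesh(mask, density, law)
    height = (config.bone_height_mm if config.bone_height_mm is not None
              else _bone_height_mm(mask, config.axis))
    step_mm = config.step_mm if config.step_mm is not None else 1e-3 * height
    max_mm = config.max_mm if config.max_mm is not None else 0.025 * height
    with _stage("boundary_conditions"):
        bc = apply_axial_compression_bc(
            mesh, axis=config.axis, layer_mm=config.layer_mm,
            step_mm=step_mm, max_mm=max_mm, support=config.support,
            top_mm=config.bc_top_mm, bottom_mm=config.bc_bottom_mm,
        )
    with _stage("solve"):
        result = solve_nonlinear(
            mesh, bc, law, tol=config.newton_tol, max_iter=config.newton_max_iter
        )
    with _stage("failure_load"):
        failure_load(result, config.criterion, bone_height_mm=height)

    report = None
    if reference_mask is not None:
        with _stage("metrics"):
            report = _metrics.compute_report(mask, reference_mask)

    if config.output_dir is not None:
        _write_outputs(config, calib, density, mesh, result)
    return result, report


def _write_outputs(config, calib, density, mesh, result) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    calib.save(out / "calibration.json")
    density.save(out / "density.nii.gz")
    mesh.save_vtk(out / "mesh.vtk")
    result.save_csv(out / "load_displacement.csv")
    cfg = {k: v for k, v in asdict(config).items()
           if isinstance(v, (int, float, str, tuple, list, type(None)))}
    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.items()},
        "seed": config.seed,
        "failure_load_N": result.failure_load,
        "criterion": result.criterion,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_sensitivity(
    ct: Volume,
    auto_mask: Mask,
    reference_mask: Mask,
    config: PipelineConfig,
) -> SensitivityReport:
    """The sensitivity experiment for one bone.

    Runs the pipeline on the reference mask, then on each of the five
    morphological variants of the automatic mask; DSC and HD are computed
    against the reference mask.  A variant whose mask vanishes or fails to
    solve is recorded as NaN and the run continues.
    """
    if auto_mask.shape != ct.shape or reference_mask.shape != ct.shape:
        raise ValueError("masks must be aligned to the CT volume")
    # anchor the load path to the reference bone's axial extent so every
    # variant is loaded between the same world planes
    if config.bc_top_mm is None:
        ax = config.axis
        occ = np.flatnonzero(
            reference_mask.data.any(axis=tuple(a for a in range(3) if a != ax))
        )
        sp, org = reference_mask.spacing[ax], reference_mask.origin[ax]
        config = replace(
            config,
            bc_bottom_mm=org + occ[0] * sp,
            bc_top_mm=org + (occ[-1] + 1) * sp,
            bone_height_mm=_bone_height_mm(reference_mask, ax),
        )
    ref_result, _ = run_failure_pipeline(ct, reference_mask, config)
    fl_ref = ref_result.failure_load

    rows = []
    for spec in VARIANT_GRID:
        row = {"dsc": np.nan, "hd_mm": np.nan, "failure_load_N": np.nan,
               "abs_diff_N": np.nan, "pct_diff": np.nan}
        try:
            variant_mask = perturb_mask(auto_mask, spec)
            row["dsc"] = _metrics.dice(variant_mask, reference_mask)
            row["hd_mm"] = _metrics.hausdorff(variant_mask, reference_mask)
            res, _ = run_failure_pipeline(ct, variant_mask, config)
            fl = res.failure_load
            row["failure_load_N"] = fl
            row["abs_diff_N"] = abs(fl - fl_ref)
            row["pct_diff"] = 100.0 * abs(fl - fl_ref) / fl_ref
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"variant {spec.label} failed: {exc}", stacklevel=2)
        rows.append(row)

    table = pd.DataFrame(rows, index=list(VARIANT_LABELS))
    return SensitivityReport(reference_failure_load_N=fl_ref, table=table)


def batch_report(
    reports: list[SensitivityReport],
) -> tuple[pd.DataFrame, dict]:
    """Aggregate sensitivity reports across bones.

    Returns a summary table (per-variant mean +/- SD of DSC and of the
    absolute/percent failure-load differences) and a statistics dict with
    the Friedman test across the reference + five variant conditions and
    Dunn post-hoc p-values of each variant against the reference.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to aggregate")
    for rep in reports:
        if tuple(rep.table.index) != VARIANT_LABELS:
            raise ValueError("heterogeneous variant sets across reports")

    summary = pd.DataFrame(index=list(VARIANT_LABELS))
    for col, label in (("dsc", "dsc"), ("abs_diff_N", "fl_abs_diff_N"),
                       ("pct_diff", "fl_pct_diff")):
        stacked = np.stack([rep.table[col].to_numpy() for rep in reports])
        summary[f"{label}_mean"] = stacked.mean(axis=0)
        summary[f"{label}_sd"] = stacked.std(axis=0, ddof=1)

    fl_matrix = np.column_stack(
        [[rep.reference_failure_load_N for rep in reports]]
        + [[rep.table.loc[lab, "failure_load_N"] for rep in reports] for lab in VARIANT_LABELS]
    )
    stats: dict = {"conditions": ("reference",) + VARIANT_LABELS}
    if np.all(np.isfinite(fl_matrix)):
        stat, p = _metrics.friedman_test(fl_matrix)
        dunn = _metrics.dunn_posthoc(fl_matrix, reference_column=0)
        stats.update(
            friedman_statistic=stat,
            friedman_p=p,
            dunn_p_adjusted={
                VARIANT_LABELS[int(j) - 1]: float(row["p_adjusted"])
                for j, row in dunn.iterrows()
            },
        )
    else:
        stats.update(friedman_statistic=np.nan, friedman_p=np.nan, dunn_p_adjusted={})
    return summary, stats
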