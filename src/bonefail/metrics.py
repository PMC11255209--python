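"""Segmentation-agreement metrics and paired nonparametric statistics.

The overlap metrics are the Sørensen–Dice score (DSC, dimensionless in
[0, 1], 1 best) and the Hausdorff distance (HD, in mm, smaller better),
computed between mask surfaces in world units.  Group comparisons across
segmentation conditions use the Friedman test on per-bone ranks, followed
by Dunn's post-hoc comparisons against a reference condition with
Bonferroni adjustment over those comparisons only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import Mask

__all__ = [
    "MetricReport",
    "dice",
    "hausdorff",
    "compute_report",
    "friedman_test",
    "dunn_posthoc",
]


@dataclass
class MetricReport:
    """Agreement between two masks: DSC and Hausdorff distance."""

    dsc: float
    hd_mm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"dsc must lie in [0, 1], got {self.dsc}")
        if self.hd_mm < 0:
            raise ValueError(f"hd_mm must be >= 0, got {self.hd_mm}")


def dice(a: Mask, b: Mask) -> float:
    """Sørensen–Dice overlap 2|A∩B| / (|A| + |B|); two empty masks -> 1."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def _surface_coords_mm(mask: Mask) -> np.ndarray:
    """World coordinates (mm) of boundary voxels (6-connectivity)."""
    data = mask.data.astype(bool)
    interior = ndimage.binary_erosion(data, ndimage.generate_binary_structure(3, 1))
    surface = data & ~interior
    idx = np.argwhere(surface)
    return idx * np.asarray(mask.spacing)


def hausdorff(a: Mask, b: Mask, percentile: float = 100.0) -> float:
    """Symmetric Hausdorff distance between mask surfaces, in mm.

    The maximum (100th-percentile) of the two directed surface-to-surface
    distances by default; ``percentile=95`` gives the robust HD95 variant.
    Distances use world units, so anisotropic spacing is respected.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.spacing != b.spacing:
        raise ValueError("masks must share voxel spacing")
    if a.data.sum() == 0 or b.data.sum() == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    pa, pb = _surface_coords_mm(a), _surface_coords_mm(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def compute_report(pred: Mask, reference: Mask, percentile: float = 100.0) -> MetricReport:
    return MetricReport(dsc=dice(pred, reference), hd_mm=hausdorff(pred, reference, percentile))


def _validate_samples(samples) -> np.ndarray:
    x = np.asarray(getattr(samples, "matrix", samples), dtype=float)
    if x.ndim != 2:
        raise ValueError("samples must be a 2-D matrix (rows=subjects, cols=conditions)")
    n, k = x.shape
    if k < 2:
        raise ValueError(f"need at least 2 conditions, got {k}")
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain missing or non-finite cells")
    return x


def _row_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)  # midranks for ties


def friedman_test(samples, exact: bool = False) -> tuple[float, float]:
    """Friedman test on a subjects x conditions matrix.

    Per-row midranks; tie-corrected chi-square statistic on k-1 degrees of
    freedom with its upper-tail p-value.  ``exact=True`` replaces the
    chi-square p by full enumeration over within-row permutations (only
    feasible for small matrices, roughly n <= 8 at k = 3).
    """
    x = _validate_samples(samples)
    n, k = x.shape
    ranks = _row_ranks(x)
    stat = _friedman_statistic(ranks, n, k)
    if exact:
        p = _friedman_exact_p(x, stat)
    else:
        p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, k - 1))
    return stat, p


def _friedman_statistic(ranks: np.ndarray, n: int, k: int) -> float:
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    den = float(np.sum(ranks**2)) - n * k * (k + 1) ** 2 / 4.0
    if den == 0.0:  # every row completely tied
        return 0.0
    return num / den


def _friedman_exact_p(x: np.ndarray, observed: float) -> float:
    n, k = x.shape
    perms = list(itertools.permutations(range(k)))
    total = len(perms) ** n
    if total > 2_000_000:
        raise ValueError(
            f"exact Friedman p-value infeasible: {total} permutations (reduce n or k)"
        )
    ranks = _row_ranks(x)
    count = 0
    for assignment in itertools.product(range(len(perms)), repeat=n):
        permuted = np.stack([ranks[i, perms[g]] for i, g in enumerate(assignment)])
        if _friedman_statistic(permuted, n, k) >= observed - 1e-12:
            count += 1
    return count / total


def dunn_posthoc(samples, reference_column: int = 0) -> pd.DataFrame:
    """Dunn's post-hoc comparisons of every condition against a reference.

    z-statistics from Friedman rank sums, two-sided normal p-values, and
    Bonferroni adjustment over the k-1 reference comparisons.  Returns a
    DataFrame indexed by compared column with ``z``, ``p`` and ``p_adjusted``.
    """
    x = _validate_samples(samples)
    n, k = x.shape
    if not (0 <= reference_column < k):
        raise ValueError(f"reference_column {reference_column} out of range for k={k}")
    ranks = _row_ranks(x)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for j in range(k):
        if j == reference_column:
            continue
        z = (mean_ranks[j] - mean_ranks[reference_column]) / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"column": j, "z": z, "p": min(1.0, p),
                     "p_adjusted": min(1.0, p * (k - 1))})
    return pd.DataFrame(rows).set_index("column")
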