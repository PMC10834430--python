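"""Segmentation-quality metrics: Dice overlap, Hausdorff distance, average
surface distance, and the fraction of surface area displaced by more than a
threshold (default 1 mm).

Surface distances are exact vertex-to-surface (point-to-triangle) values,
not vertex-to-vertex approximations. The Hausdorff distance is symmetric:
the maximum over both directed vertex-to-surface distance sets; the average
distance is the mean of the two directed sets concatenated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh_core import GridSpec, TriMesh, VoxelMask, mask_to_surface, voxelize_surface

__all__ = [
    "DistanceReport",
    "MetricsReport",
    "dice",
    "iou",
    "surface_distances",
    "area_fraction_over",
    "evaluate_segmentation",
    "report_to_csv",
]


@dataclass
class DistanceReport:
    """Directed vertex-to-surface distances between two meshes (mm)."""

    per_vertex_pred_to_gt: np.ndarray
    per_vertex_gt_to_pred: np.ndarray

    @property
    def hausdorff(self) -> float:
        return float(max(self.per_vertex_pred_to_gt.max(), self.per_vertex_gt_to_pred.max()))

    @property
    def average(self) -> float:
        return float(
            np.concatenate([self.per_vertex_pred_to_gt, self.per_vertex_gt_to_pred]).mean()
        )


@dataclass
class MetricsReport:
    """The four segmentation-evaluation metrics, plus IoU for reference.

    dsc is a fraction in [0, 1]; `dsc_pct` gives the x100 convention used
    in segmentation reports.
    """

    dsc: float
    hausdorff_mm: float
    average_mm: float
    area_fraction_gt_1mm: float
    iou: float = None

    def __post_init__(self):
        if not 0 <= self.dsc <= 1:
            raise ValueError("dsc must be in [0, 1]")
        if not 0 <= self.area_fraction_gt_1mm <= 100:
            raise ValueError("area fraction must be a percentage in [0, 100]")

    @property
    def dsc_pct(self) -> float:
        return 100.0 * self.dsc


def _check_grids(a: VoxelMask, b: VoxelMask):
    if not a.same_grid(b):
        raise ValueError("masks are on different grids (spacing/origin/shape mismatch)")


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) on identical grids."""
    _check_grids(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def iou(a: VoxelMask, b: VoxelMask) -> float:
    """Intersection over union |A∩B| / |A∪B| on identical grids."""
    _check_grids(a, b)
    union = int(np.logical_or(a.values, b.values).sum())
    if union == 0:
        warnings.warn("iou of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return inter / union


def surface_distances(pred: TriMesh, gt: TriMesh) -> DistanceReport:
    """Exact directed vertex-to-surface distances in both directions."""
    if len(pred.faces) == 0 or len(gt.faces) == 0:
        raise ValueError("both meshes must have faces")
    d_pg = gt.surface_query().distance(pred.vertices)
    d_gp = pred.surface_query().distance(gt.vertices)
    return DistanceReport(d_pg, d_gp)


def area_fraction_over(pred: TriMesh, gt: TriMesh, threshold: float = 1.0) -> float:
    """Percent of predicted surface area farther than `threshold` mm from gt.

    Each predicted vertex owns one third of its incident triangle area; the
    returned value is the owned area of vertices whose distance to the
    ground-truth surface exceeds the threshold, as a percentage of the total
    predicted area.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (mm)")
    d = gt.surface_query().distance(pred.vertices)
    va = pred.vertex_areas()
    total = va.sum()
    if total == 0:
        raise ValueError("predicted mesh has zero area")
    return float(100.0 * va[d > threshold].sum() / total)


def evaluate_segmentation(pred, gt, grid: GridSpec | None = None, threshold: float = 1.0) -> MetricsReport:
    """All four metrics between a prediction and ground truth.

    Inputs may be meshes, masks, or one of each. Surface metrics need
    meshes (masks are converted by marching cubes); the Dice overlap needs
    masks (meshes are voxelized). When a mesh must be voxelized, the grid of
    the ground-truth mask is used if available, otherwise `grid` must be
    given.
    """
    pred_mask = pred if isinstance(pred, VoxelMask) else None
    gt_mask = gt if isinstance(gt, VoxelMask) else None
    if grid is None:
        for m in (gt_mask, pred_mask):
            if m is not None:
                grid = GridSpec(m.spacing, m.origin, m.shape)
                break
    if grid is None:
        raise ValueError("a grid spec is required when both inputs are meshes")

    pred_mesh = pred if isinstance(pred, TriMesh) else mask_to_surface(pred)
    gt_mesh = gt if isinstance(gt, TriMesh) else mask_to_surface(gt)
    if pred_mask is None:
        pred_mask = voxelize_surface(pred_mesh, grid)
    if gt_mask is None:
        gt_mask = voxelize_surface(gt_mesh, grid)

    dist = surface_distances(pred_mesh, gt_mesh)
    return MetricsReport(
        dsc=dice(pred_mask, gt_mask),
        hausdorff_mm=dist.hausdorff,
        average_mm=dist.average,
        area_fraction_gt_1mm=area_fraction_over(pred_mesh, gt_mesh, threshold),
        iou=iou(pred_mask, gt_mask),
    )


def report_to_csv(reports, path, labels=None) -> pd.DataFrame:
    """Write MetricsReport rows to CSV with the standard column layout."""
    if isinstance(reports, MetricsReport):
        reports = [reports]
    frame = pd.DataFrame(
        [
            {
                "dsc": r.dsc,
                "hausdorff_mm": r.hausdorff_mm,
                "average_mm": r.average_mm,
                "delta_area_pct_gt_1mm": r.area_fraction_gt_1mm,
            }
            for r in reports
        ],
        index=labels,
    )
    frame.to_csv(path, index=labels is not None)
    return frame
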