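"""Segmentation evaluation: Dice, Hausdorff, centerline overlap.

Because reference annotations rarely cover every vessel in a volume, all
three metrics can be restricted to the neighbourhood of the annotated
tree: :func:`evaluation_mask` labels every voxel within six local radii of
the reference centerline, and :func:`evaluate` applies it to both masks
before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .centerline import CenterlineTree
from .errors import EmptyCenterline, EmptySet, ShapeMismatch
from .volume import ImageVolume, LabelVolume

__all__ = [
    "MetricReport",
    "dice",
    "hausdorff",
    "centerline_overlap",
    "evaluation_mask",
    "evaluate",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class MetricReport:
    dice: float
    hausdorff: float
    hausdorff_units: str
    centerline_overlap: float
    mask_applied: bool

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "hausdorff": self.hausdorff,
            "hausdorff_units": self.hausdorff_units,
            "centerline_overlap": self.centerline_overlap,
            "mask_applied": self.mask_applied,
        }


def _data(x) -> np.ndarray:
    return np.asarray(x.data if isinstance(x, ImageVolume) else x)


def dice(X, Y) -> float:
    """Overlap score ``2|X n Y| / (|X| + |Y|)``; 0 when both sets are empty."""
    x = _data(X) > 0.5
    y = _data(Y) > 0.5
    if x.shape != y.shape:
        raise ShapeMismatch(f"{x.shape} vs {y.shape}")
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((x & y).sum()) / denom


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices of foreground voxels with at least one background 6-neighbor."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return np.argwhere(mask & ~eroded)


def hausdorff(X, Y, units: Literal["pixels", "mm"] = "pixels", spacing=None) -> float:
    """Symmetric Hausdorff distance between the two mask boundaries.

    Computed on boundary voxels (the surfaces, not the filled volumes); in
    ``pixels`` the distance is in index units, in ``mm`` indices are scaled
    by ``spacing`` first.
    """
    x = _data(X) > 0.5
    y = _data(Y) > 0.5
    if x.shape != y.shape:
        raise ShapeMismatch(f"{x.shape} vs {y.shape}")
    if not x.any() or not y.any():
        raise EmptySet("hausdorff needs two nonempty masks")
    bx = _boundary_voxels(x).astype(float)
    by = _boundary_voxels(y).astype(float)
    if units == "mm":
        if spacing is None:
            spacing = getattr(X, "spacing", None)
        if spacing is None:
            raise ValueError("mm units require a spacing")
        bx = bx * np.asarray(spacing, float)[None, :]
        by = by * np.asarray(spacing, float)[None, :]
    d_xy = cKDTree(by).query(bx)[0].max()
    d_yx = cKDTree(bx).query(by)[0].max()
    return float(max(d_xy, d_yx))


def centerline_overlap(Y, Ct: CenterlineTree, sample_interval: float | None = None) -> float:
    """Fraction of reference-centerline length inside the predicted mask.

    The tree is discretized at sub-voxel intervals and the mask is sampled
    at every point; the line integral is taken by the trapezoid rule along
    each branch.
    """
    y = _data(Y)
    vol = Y if isinstance(Y, ImageVolume) else None
    if vol is None:
        raise ValueError("centerline_overlap needs a volume with grid metadata")
    if Ct is None or not Ct.branches or Ct.total_length <= 0:
        raise EmptyCenterline("reference centerline has no length")
    if sample_interval is None:
        sample_interval = 0.25 * float(vol.spacing.min())
    inside_len = 0.0
    total_len = 0.0
    for branch in Ct.branches:
        rb = branch.resample(sample_interval)
        idx = np.round(vol.world_to_index(rb.points)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(vol.shape)[None, :]), axis=1)
        inside = np.zeros(len(idx))
        inside[ok] = (y[tuple(idx[ok].T)] > 0.5).astype(float)
        seg = np.linalg.norm(np.diff(rb.points, axis=0), axis=1)
        inside_len += float((0.5 * (inside[:-1] + inside[1:]) * seg).sum())
        total_len += float(seg.sum())
    return inside_len / total_len


def evaluation_mask(
    Ct: CenterlineTree,
    reference: ImageVolume,
    radius_multiple: float = 6.0,
) -> LabelVolume:
    """Voxels within ``radius_multiple`` local radii of the reference tree.

    Each voxel is tested against its *nearest* centerline sample: inside
    iff the distance is at most ``radius_multiple`` times that sample's
    radius.  Metrics are restricted to this region so that unannotated
    vessels do not count against a prediction.
    """
    if Ct is None or not Ct.branches:
        raise EmptyCenterline("cannot build a mask from an empty centerline")
    interval = 0.5 * float(reference.spacing.min())
    pts, radii = Ct.all_samples(interval)
    kdt = cKDTree(pts)
    mask = np.zeros(reference.shape, dtype=np.uint8)

    reach = radius_multiple * float(radii.max())
    lo = np.maximum(
        np.floor((pts.min(axis=0) - reach - reference.origin) / reference.spacing), 0
    ).astype(int)
    hi = np.minimum(
        np.ceil((pts.max(axis=0) + reach - reference.origin) / reference.spacing),
        np.array(reference.shape) - 1,
    ).astype(int)
    axes = [
        reference.origin[a] + np.arange(lo[a], hi[a] + 1) * reference.spacing[a]
        for a in range(3)
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d, nearest = kdt.query(grid, workers=-1)
    inside = d <= radius_multiple * radii[nearest]
    sub = inside.reshape(tuple(hi - lo + 1)).astype(np.uint8)
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = sub
    return LabelVolume(mask, reference.spacing.copy(), reference.origin.copy())


def evaluate(
    pred: LabelVolume,
    truth: LabelVolume,
    centerline: CenterlineTree | None = None,
    mask_six_radius: bool = False,
    hausdorff_units: Literal["pixels", "mm"] = "pixels",
) -> MetricReport:
    """Full metric report, optionally within the six-radius region."""
    if pred.shape != truth.shape:
        raise ShapeMismatch(f"{pred.shape} vs {truth.shape}")
    p = _data(pred) > 0.5
    t = _data(truth) > 0.5
    masked = False
    if mask_six_radius:
        if centerline is None:
            raise EmptyCenterline("six-radius masking requires a centerline")
        m = _data(evaluation_mask(centerline, truth)) > 0.5
        p = p & m
        t = t & m
        masked = True
    pv = LabelVolume(p.astype(np.uint8), pred.spacing, pred.origin)
    tv = LabelVolume(t.astype(np.uint8), truth.spacing, truth.origin)
    co = float("nan")
    if centerline is not None:
        co = centerline_overlap(pv, centerline)
    return MetricReport(
        dice=dice(pv, tv),
        hausdorff=hausdorff(pv, tv, units=hausdorff_units, spacing=pred.spacing),
        hausdorff_units=hausdorff_units,
        centerline_overlap=co,
        mask_applied=masked,
    )


def wilcoxon_signed_rank(scores_a, scores_b):
    """Paired Wilcoxon signed-rank test between two sets of metric scores.

    Thin wrapper over :func:`scipy.stats.wilcoxon`; returns
    ``(statistic, p_value)``.
    """
    from scipy import stats

    res = stats.wilcoxon(np.asarray(scores_a, float), np.asarray(scores_b, float))
    return float(res.statistic), float(res.pvalue)
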