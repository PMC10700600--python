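"""Segmentation-agreement metrics and method-agreement statistics.

Overlap metrics (IoU, precision, recall, Dice) derive from per-volume
voxel confusion counts.  The 95th-percentile Hausdorff distance is
computed between 6-connected boundary voxels with anisotropic voxel
spacing honored, combining the two directed distances by their maximum.
Bland-Altman agreement uses the approximate confidence intervals on the
mean difference and on each +-1.96 SD limit of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ConfusionCounts", "OverlapMetrics", "AgreementReport",
    "confusion", "overlap_metrics", "boundary_voxels", "hd95",
    "bland_altman", "HD95_COMBINATION",
]

#: How the two directed 95th-percentile distances are combined.
HD95_COMBINATION = "max-of-directed-percentiles"


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-volume voxel counts: TP is the intersection of prediction and
    truth, TN the part of the volume beyond their union, FP the predicted
    voxels not in the truth, FN the missed truth voxels."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary_pair(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a.astype(bool), b.astype(bool)


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Exact voxel confusion counts between two binary masks."""
    p, t = _check_binary_pair(pred_mask, truth_mask)
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class OverlapMetrics:
    """Overlap ratios in [0, 1]; a None field marks an undefined ratio
    (zero denominator), deliberately distinct from 0."""

    iou: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    dice: Optional[float]


def overlap_metrics(counts: ConfusionCounts) -> OverlapMetrics:
    """IoU, precision, recall and Dice from confusion counts."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    iou = tp / (tp + fp + fn) if (tp + fp + fn) > 0 else None
    dice = 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return OverlapMetrics(iou=iou, precision=precision, recall=recall,
                          dice=dice)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background face-neighbour.

    Voxels on the array edge count as boundary (the outside is
    background).  Uses the 6-connected structuring element.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3-D mask")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure,
                                      border_value=0)
    return mask & ~interior


def hd95(mask_a: np.ndarray, mask_b: np.ndarray,
         voxel_size=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile Hausdorff distance between mask boundaries, in mm.

    Directed distances run from each boundary voxel of one mask to the
    nearest boundary voxel of the other (Euclidean, anisotropic spacing
    honored); the reported value is the maximum of the two directed 95th
    percentiles (linear-interpolation percentile).  Symmetric, >= 0, and
    0 for identical masks.  Raises ``ValueError`` on an empty mask --
    the caller should treat that as a QC failure, not a distance.
    """
    a, b = _check_binary_pair(mask_a, mask_b)
    if not a.any() or not b.any():
        raise ValueError("hd95 undefined for an empty mask")
    ba = boundary_voxels(a)
    bb = boundary_voxels(b)
    sampling = tuple(float(v) for v in voxel_size)
    # distance from every voxel to the nearest boundary voxel of each mask
    dist_to_bb = ndimage.distance_transform_edt(~bb, sampling=sampling)
    dist_to_ba = ndimage.distance_transform_edt(~ba, sampling=sampling)
    d_ab = dist_to_bb[ba]
    d_ba = dist_to_ba[bb]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


@dataclass
class AgreementReport:
    """Bland-Altman agreement between two paired measurement series."""

    n: int
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    ci_mean: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    differences: np.ndarray
    means: np.ndarray


def bland_altman(values_a, values_b) -> AgreementReport:
    """Mean difference, +-1.96 SD limits of agreement, and approximate CIs.

    CI of the mean difference: ``d +- t(0.975, n-1) * SD / sqrt(n)``;
    CI of each limit of agreement: ``LoA +- t(0.975, n-1) * sqrt(3 SD^2 / n)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D series of equal length required")
    n = len(a)
    if n < 3:
        raise ValueError("Bland-Altman analysis requires n >= 3 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo = mean - 1.96 * sd
    loa_hi = mean + 1.96 * sd
    tq = float(stats.t.ppf(0.975, n - 1))
    hw_mean = tq * sd / np.sqrt(n)
    hw_loa = tq * np.sqrt(3.0 * sd * sd / n)
    return AgreementReport(
        n=n, mean_difference=mean, sd_difference=sd,
        loa_lower=loa_lo, loa_upper=loa_hi,
        ci_mean=(mean - hw_mean, mean + hw_mean),
        ci_loa_lower=(loa_lo - hw_loa, loa_lo + hw_loa),
        ci_loa_upper=(loa_hi - hw_loa, loa_hi + hw_loa),
        differences=d, means=(a + b) / 2.0)
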