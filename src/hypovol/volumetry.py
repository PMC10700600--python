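"""Volume quantification, ICV normalization, and IQR quality control.

The normalized structure volume is

    V_norm = V_target / V_ICV * mean_control_ICV,

i.e. the individual volume rescaled by the ratio of the control-group
mean intracranial volume to the subject's own, which removes head-size
variance while keeping the result in mm^3 on the control scale.

Quality control rejects subjects per group through a fixed cascade --
empty segmentation, ICV outlier, raw target outlier, normalized-volume
outlier -- using Tukey IQR fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR]
computed once per stage on the survivors of the previous stage (no
iterative re-fencing), so re-running QC on the accepted subset with the
stored fences flags nobody new.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SubjectRecord", "NormalizationReference", "OutlierFences", "QCResult",
    "mask_volume", "normalize_volume", "iqr_fences", "qc_cohort",
    "pooled_rates", "QC_REASONS",
]

QC_REASONS = ("none", "empty_segmentation", "icv_outlier", "target_outlier",
              "normalized_outlier")


@dataclass
class SubjectRecord:
    """Per-subject volumes and QC outcome (volumes in mm^3)."""

    subject_id: str
    group: str
    v_target: Optional[float] = None
    v_icv: Optional[float] = None
    v_norm: Optional[float] = None
    qc_status: str = "accepted"
    qc_reason: str = "none"


@dataclass(frozen=True)
class NormalizationReference:
    """Control-group mean intracranial volume, mm^3."""

    mean_control_icv: float

    def __post_init__(self):
        if self.mean_control_icv <= 0:
            raise ValueError("mean_control_icv must be > 0")


@dataclass(frozen=True)
class OutlierFences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def mask_volume(mask: np.ndarray, voxel_size) -> float:
    """Foreground voxel count times voxel volume, in mm^3.

    Left and right components of a bilateral structure are simply part
    of the same mask and therefore summed.  Raises on non-binary input.
    """
    arr = np.asarray(mask)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (bool or {0,1})")
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel sizes must be > 0")
    return float(arr.astype(bool).sum()) * float(np.prod(voxel_size))


def normalize_volume(v_target: float, v_icv: float,
                     ref: NormalizationReference) -> float:
    """Head-size-normalized structure volume (mm^3)."""
    if v_icv <= 0:
        raise ValueError("v_icv must be > 0")
    return v_target / v_icv * ref.mean_control_icv


def iqr_fences(values) -> OutlierFences:
    """Tukey fences from linearly interpolated quartiles (type-7)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError("IQR fences require at least 4 values")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    return OutlierFences(q1=float(q1), q3=float(q3), iqr=float(iqr),
                         lower=float(q1 - 1.5 * iqr),
                         upper=float(q3 + 1.5 * iqr))


@dataclass
class QCResult:
    """QC outcome: mutated records, frozen fences, and acceptance rates."""

    records: list[SubjectRecord]
    fences: dict = field(default_factory=dict)
    reference: Optional[NormalizationReference] = None
    acceptance_rate: float = 1.0
    acceptance_rate_by_group: dict = field(default_factory=dict)
    rejected_by_group: dict = field(default_factory=dict)


def _accepted(records, group=None):
    return [r for r in records if r.qc_status == "accepted"
            and (group is None or r.group == group)]


def qc_cohort(records: Sequence[SubjectRecord],
              reference: Optional[NormalizationReference] = None) -> QCResult:
    """Run the rejection cascade and fill qc_status/qc_reason per subject.

    Stages, each per group with fences frozen from that stage's
    survivors: (1) empty target or ICV segmentation; (2) ICV outlier;
    (3) raw target-volume outlier; (4) normalized-volume outlier.  Each
    rejected subject carries the first-triggered reason.  The
    normalization reference defaults to the mean ICV of the controls
    accepted through stage 3.
    """
    records = list(records)
    for rec in records:
        if rec.v_target is None or rec.v_icv is None:
            raise ValueError(f"subject {rec.subject_id}: volumes missing")
    groups = sorted({r.group for r in records})
    result = QCResult(records=records)

    # stage 1: empty segmentations
    for rec in records:
        if rec.v_target <= 0 or rec.v_icv <= 0:
            rec.qc_status, rec.qc_reason = "rejected", "empty_segmentation"

    # stages 2 and 3: raw-volume fences per group
    for stage, attr, reason in ((2, "v_icv", "icv_outlier"),
                                (3, "v_target", "target_outlier")):
        for group in groups:
            survivors = _accepted(records, group)
            if len(survivors) < 4:   # quartiles not estimable; skip stage
                continue
            fences = iqr_fences([getattr(r, attr) for r in survivors])
            result.fences[(group, reason)] = fences
            for rec in survivors:
                if not fences.contains(getattr(rec, attr)):
                    rec.qc_status, rec.qc_reason = "rejected", reason

    # stage 4: normalized volumes
    if reference is None:
        controls = _accepted(records, "control")
        if not controls:
            raise ValueError("no accepted control subjects to define the "
                             "normalization reference")
        reference = NormalizationReference(
            mean_control_icv=float(np.mean([r.v_icv for r in controls])))
    result.reference = reference
    for rec in _accepted(records):
        rec.v_norm = normalize_volume(rec.v_target, rec.v_icv, reference)
    for group in groups:
        survivors = _accepted(records, group)
        if len(survivors) < 4:
            continue
        fences = iqr_fences([r.v_norm for r in survivors])
        result.fences[(group, "normalized_outlier")] = fences
        for rec in survivors:
            if not fences.contains(rec.v_norm):
                rec.qc_status, rec.qc_reason = "rejected", "normalized_outlier"

    totals = {g: sum(1 for r in records if r.group == g) for g in groups}
    rejected = {g: sum(1 for r in records
                       if r.group == g and r.qc_status == "rejected")
                for g in groups}
    rates = pooled_rates(rejected, totals)
    result.rejected_by_group = rejected
    result.acceptance_rate = rates["acceptance_rate"]
    result.acceptance_rate_by_group = rates["acceptance_rate_by_group"]
    return result


def pooled_rates(rejected: Mapping[str, int],
                 totals: Mapping[str, int]) -> dict:
    """Per-group and pooled rejection/acceptance accounting.

    Rates are fractions in [0, 1]; the pooled rate is total rejected
    over total subjects, consistent with the per-group accounting.
    """
    if set(rejected) != set(totals):
        raise ValueError("rejected and totals must cover the same groups")
    n_total = sum(totals.values())
    n_rej = sum(rejected.values())
    if n_total <= 0:
        raise ValueError("totals must be positive")
    return {
        "rejection_rate": n_rej / n_total,
        "acceptance_rate": 1.0 - n_rej / n_total,
        "rejection_rate_by_group": {g: rejected[g] / totals[g]
                                    for g in totals},
        "acceptance_rate_by_group": {g: 1.0 - rejected[g] / totals[g]
                                     for g in totals},
        "n_rejected": n_rej,
        "n_total": n_total,
    }
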