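"""Synthetic T1-like head phantoms with known structure and ICV masks.

The phantom is deliberately simple: a bright ellipsoidal intracranial
compartment on a dark background, containing a small bilateral midline
target structure (two mirrored half-ellipsoids flanking a midline plane,
like the hypothalamus flanking the third ventricle) at a configurable
intensity offset from the surrounding tissue.  Every generated volume
carries its ground-truth masks and true volumes, so the whole
segmentation/volumetry pipeline can be exercised and scored without
patient data.

Cohorts add the group structure of an atrophy study: per-subject target
volumes drawn log-normally around a group mean (the case mean reduced by
``effect_fraction``), per-subject intracranial volumes, and per-scan
global contrast variation.  The target volume is coupled proportionally
to the subject's ICV, so that ICV normalization removes head-size
variance the way it does in real morphometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "PhantomParameterError",
    "PhantomSpec",
    "LabeledVolume",
    "CohortSpec",
    "generate_phantom",
    "draw_cohort_parameters",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "TARGET_ASPECT",
]

#: Fixed aspect ratio (x, y, z) of the bilateral target: slightly wider than
#: tall in-plane and elongated along the slice axis so it spans many slices,
#: producing low-signal anterior/posterior edge slices.
TARGET_ASPECT = (1.0, 1.2, 2.0)


class PhantomParameterError(ValueError):
    """A phantom parameter violates a geometric or physical constraint."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic head volume.

    Defaults are the desk-scale geometry: a 64x64x24 grid at
    0.75x0.75x1.0 mm, an ~14 cm^3 intracranial ellipsoid and a 300 mm^3
    target.  ``full_scale`` gives the clinical-scale block geometry
    (512x512 in-plane at 0.125 mm, 50 slices of 0.5 mm).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size: tuple[float, float, float] = (0.75, 0.75, 1.0)
    icv_semiaxes: tuple[float, float, float] = (20.0, 21.0, 8.0)
    target_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_volume: float = 300.0
    intensity_background: float = 0.10
    intensity_tissue: float = 0.75
    target_contrast: float = 0.20
    noise_sd: float = 0.02
    contrast_gain: float = 1.0
    contrast_offset: float = 0.0
    contrast_gamma: float = 1.0
    bias_gradient: float = 0.0
    seed: int = 0

    @classmethod
    def full_scale(cls, **overrides) -> "PhantomSpec":
        """Clinical-scale 50-slice block: 512x512 px at 0.125 mm, 0.5 mm slices."""
        base = dict(
            grid_shape=(512, 512, 50),
            voxel_size=(0.125, 0.125, 0.5),
            icv_semiaxes=(28.0, 28.0, 40.0),
            target_volume=820.0,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise PhantomParameterError("voxel_size components must be > 0")
        if any(n < 4 for n in self.grid_shape):
            raise PhantomParameterError("grid_shape components must be >= 4")
        if any(a <= 0 for a in self.icv_semiaxes):
            raise PhantomParameterError("icv_semiaxes must be > 0")
        if self.target_volume <= 0:
            raise PhantomParameterError("target_volume must be > 0")
        if self.contrast_gamma <= 0:
            raise PhantomParameterError("contrast_gamma must be > 0")
        if self.noise_sd < 0:
            raise PhantomParameterError("noise_sd must be >= 0")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def target_semiaxes(self) -> tuple[float, float, float]:
        """Semi-axes of each constituent ellipsoid given the total volume.

        The target is two mirrored half-ellipsoids, so the total volume
        equals the volume of one full ellipsoid, (4/3) pi a b c.
        """
        ax, ay, az = TARGET_ASPECT
        scale = (3.0 * self.target_volume / (4.0 * np.pi * ax * ay * az)) ** (1.0 / 3.0)
        return (ax * scale, ay * scale, az * scale)


@dataclass
class LabeledVolume:
    """A 3-D intensity grid with voxel geometry and optional ground-truth masks.

    ``true_*_volume`` always equals the mask voxel count times the voxel
    volume (mm^3).  The slice axis is the third array axis (coronal
    stand-in); world coordinates are ``index * voxel_size`` in mm.
    """

    intensity: np.ndarray
    voxel_size: tuple[float, float, float]
    target_mask: Optional[np.ndarray] = None
    icv_mask: Optional[np.ndarray] = None
    true_target_volume: Optional[float] = None
    true_icv_volume: Optional[float] = None
    subject_id: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("target_mask", "icv_mask"):
            m = getattr(self, name)
            if m is not None and m.shape != self.intensity.shape:
                raise ValueError(f"{name} shape {m.shape} != intensity shape "
                                 f"{self.intensity.shape}")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


def _world_grids(shape, voxel_size):
    axes = [np.arange(n, dtype=np.float64) * d for n, d in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Generate one synthetic head volume with target and ICV masks.

    Deterministic per seed: the same spec always yields bit-identical
    grids.  Raises :class:`PhantomParameterError` when the requested
    target does not fit strictly inside the intracranial compartment.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    X, Y, Z = _world_grids(shape, spec.voxel_size)
    center = tuple((n - 1) / 2.0 * d for n, d in zip(shape, spec.voxel_size))

    ia, ib, ic = spec.icv_semiaxes
    icv = (((X - center[0]) / ia) ** 2
           + ((Y - center[1]) / ib) ** 2
           + ((Z - center[2]) / ic) ** 2) <= 1.0

    target = _target_mask(spec, shape, center)

    # Strict containment: the target (including its outer surface) must
    # lie inside the compartment, not merely overlap it.
    interior = _erode6(icv)
    if not target.any():
        raise PhantomParameterError(
            "target_volume too small: no voxel centers fall inside the target "
            "surface at this grid resolution")
    if np.any(target & ~interior):
        raise PhantomParameterError(
            "target_volume/target_center violate containment: target mask must "
            "lie strictly inside the intracranial compartment")

    base = np.full(shape, spec.intensity_background, dtype=np.float64)
    base[icv] = spec.intensity_tissue
    base[target] += spec.target_contrast
    if spec.bias_gradient != 0.0:
        ramp = np.linspace(-0.5, 0.5, shape[0])[:, None, None]
        base = base * (1.0 + spec.bias_gradient * ramp)

    # Per-scan global contrast transform, then acquisition noise.
    img = spec.contrast_gain * np.clip(base, 0.0, None) ** spec.contrast_gamma \
        + spec.contrast_offset
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)

    vv = spec.voxel_volume
    return LabeledVolume(
        intensity=img,
        voxel_size=tuple(spec.voxel_size),
        target_mask=target,
        icv_mask=icv,
        true_target_volume=float(target.sum()) * vv,
        true_icv_volume=float(icv.sum()) * vv,
    )


def _target_mask(spec: PhantomSpec, shape, center) -> np.ndarray:
    """Voxelize the bilateral target by sub-voxel occupancy.

    The target is two mirrored half-ellipsoids whose flat faces flank
    the midline plane, separated by one in-plane voxel.  Each voxel in
    the target bounding box is sampled on a 3x3x3 sub-grid and included
    when at least half its volume lies inside the analytic shape; this
    keeps the realized volume unbiased regardless of how the cut planes
    align with the voxel grid.
    """
    ta, tb, tc = spec.target_semiaxes()
    d = spec.voxel_size
    tcen = tuple(center[k] + spec.target_center[k] for k in range(3))
    # Flat cut faces are snapped to half-integer grid coordinates
    # (midway between voxel columns) so boundary voxels are never split
    # lengthwise by the plane, keeping the voxelized volume unbiased.
    dx = d[0]
    plane_l = (round((tcen[0] - dx / 2.0) / dx - 0.5) + 0.5) * dx
    plane_r = (round((tcen[0] + dx / 2.0) / dx - 0.5) + 0.5) * dx
    if plane_r <= plane_l:
        plane_r = plane_l + dx

    lo = [max(0, int(np.floor((c - e) / d[k])) - 1)
          for k, (c, e) in enumerate(zip(
              (plane_l, tcen[1], tcen[2]), (ta, tb, tc)))]
    hi = [min(shape[k], int(np.ceil((c + e) / d[k])) + 2)
          for k, (c, e) in enumerate(zip(
              (plane_r, tcen[1], tcen[2]), (ta, tb, tc)))]

    sub = 3
    offs = (np.arange(sub) + 0.5) / sub - 0.5
    idx = [np.arange(lo[k], hi[k], dtype=np.float64) for k in range(3)]
    frac = np.zeros([len(i) for i in idx])
    for ox in offs:
        xw = (idx[0] + ox)[:, None, None] * d[0]
        for oy in offs:
            yw = (idx[1] + oy)[None, :, None] * d[1]
            for oz in offs:
                zw = (idx[2] + oz)[None, None, :] * d[2]
                inside = np.zeros(frac.shape, dtype=bool)
                for side, cx in ((-1.0, plane_l), (+1.0, plane_r)):
                    ell = (((xw - cx) / ta) ** 2
                           + ((yw - tcen[1]) / tb) ** 2
                           + ((zw - tcen[2]) / tc) ** 2) <= 1.0
                    inside |= ell & ((xw * side) >= (cx * side))
                frac += inside
    frac /= sub ** 3
    # Keep the round(sum of occupancy fractions) highest-occupancy voxels:
    # the voxel count then tracks the analytic volume to within one voxel
    # instead of wobbling with how the surface cuts the grid.
    n_keep = min(int(round(frac.sum())), int((frac > 0).sum()))
    box = np.zeros(frac.shape, dtype=bool)
    if n_keep > 0:
        order = np.argsort(-frac, axis=None, kind="stable")[:n_keep]
        box.flat[order] = True
    target = np.zeros(shape, dtype=bool)
    target[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = box
    return target


def _erode6(mask: np.ndarray) -> np.ndarray:
    """Binary erosion with the 6-connected structuring element, edges = background."""
    out = mask.copy()
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(mask, shift, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            rolled[tuple(edge)] = False
            out &= rolled
    return out


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group phantom cohort (control vs case).

    ``effect_fraction`` is the fractional reduction of the case-group
    mean target volume (0.10 = 10% atrophy).  ``between_subject_cv`` is
    the coefficient of variation of the head-size-normalized target
    volume; the raw target volume additionally scales proportionally
    with the subject's drawn ICV.
    """

    n_control: int = 20
    n_case: int = 20
    control_mean_target_volume: float = 300.0
    effect_fraction: float = 0.10
    between_subject_cv: float = 0.08
    icv_mean: float = 14000.0
    icv_sd: float = 1200.0
    contrast_gain_range: tuple[float, float] = (0.9, 1.1)
    contrast_offset_range: tuple[float, float] = (-0.05, 0.05)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.effect_fraction < 1.0):
            raise ValueError("effect_fraction must be in [0, 1)")
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("group sizes must be >= 1")
        if self.control_mean_target_volume <= 0 or self.icv_mean <= 0:
            raise ValueError("mean volumes must be > 0")
        if self.between_subject_cv < 0 or self.icv_sd < 0:
            raise ValueError("dispersions must be >= 0")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def draw_cohort_parameters(cohort: CohortSpec) -> pd.DataFrame:
    """Draw the per-subject cohort parameters (no image synthesis).

    Returns a frame with subject_id, group, the normalized and raw true
    target volumes, the drawn ICV and per-scan contrast parameters, and
    a per-subject phantom seed.  This is the sampling stage of
    :func:`generate_cohort`, exposed so distributional properties can be
    checked cheaply at large n.
    """
    cohort.validate()
    ss = np.random.SeedSequence(cohort.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    groups = [("control", cohort.n_control), ("case", cohort.n_case)]
    idx = 0
    for group, n in groups:
        mean = cohort.control_mean_target_volume
        if group == "case":
            mean *= 1.0 - cohort.effect_fraction
        for _ in range(n):
            if cohort.between_subject_cv > 0:
                mu, sig = _lognormal_params(mean, cohort.between_subject_cv)
                v_norm = float(rng.lognormal(mu, sig))
            else:
                v_norm = mean
            icv = float(rng.normal(cohort.icv_mean, cohort.icv_sd)) \
                if cohort.icv_sd > 0 else cohort.icv_mean
            # Truncate pathological draws; resample keeps positivity.
            tries = 0
            while icv <= 0.2 * cohort.icv_mean:
                icv = float(rng.normal(cohort.icv_mean, cohort.icv_sd))
                tries += 1
                if tries > 100:  # pragma: no cover - sd would have to be absurd
                    raise ValueError("icv_sd too large: cannot draw positive ICV")
            v_raw = v_norm * icv / cohort.icv_mean
            gain = float(rng.uniform(*cohort.contrast_gain_range))
            offset = float(rng.uniform(*cohort.contrast_offset_range))
            rows.append(dict(
                subject_id=f"sub-{idx:04d}", group=group,
                true_norm_target_volume=v_norm, true_target_volume=v_raw,
                true_icv_volume=icv, contrast_gain=gain,
                contrast_offset=offset,
            ))
            idx += 1
    frame = pd.DataFrame(rows)
    child_seeds = ss.spawn(len(frame) + 1)[1:]
    frame["phantom_seed"] = [int(c.generate_state(1)[0] % (2 ** 31))
                             for c in child_seeds]
    return frame


def generate_cohort(cohort: CohortSpec) -> list[LabeledVolume]:
    """Generate the full cohort of labeled phantom volumes."""
    params = draw_cohort_parameters(cohort)
    base = cohort.phantom
    base_icv_volume = 4.0 / 3.0 * np.pi * float(np.prod(base.icv_semiaxes))
    volumes = []
    for row in params.itertuples(index=False):
        f = (row.true_icv_volume / base_icv_volume) ** (1.0 / 3.0)
        spec = dataclasses.replace(
            base,
            icv_semiaxes=tuple(a * f for a in base.icv_semiaxes),
            target_volume=row.true_target_volume,
            contrast_gain=base.contrast_gain * row.contrast_gain,
            contrast_offset=base.contrast_offset + row.contrast_offset,
            seed=int(row.phantom_seed),
        )
        vol = generate_phantom(spec)
        vol.subject_id = row.subject_id
        vol.group = row.group
        volumes.append(vol)
    return volumes


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_cohort(volumes: Sequence[LabeledVolume], directory) -> Path:
    """Write each volume and its masks as NIfTI-1 plus a CSV manifest.

    Returns the manifest path.  Round-trips losslessly through
    :func:`read_cohort` (intensities stored as float64, masks as uint8,
    voxel sizes in the affine).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, vol in enumerate(volumes):
        sid = vol.subject_id or f"sub-{i:04d}"
        aff = _affine(vol.voxel_size)
        paths = {}
        nib.save(nib.Nifti1Image(vol.intensity.astype(np.float64), aff),
                 str(directory / f"{sid}_t1.nii"))
        paths["t1_path"] = f"{sid}_t1.nii"
        for key, mask in (("target", vol.target_mask), ("icv", vol.icv_mask)):
            if mask is not None:
                nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff),
                         str(directory / f"{sid}_{key}.nii"))
                paths[f"{key}_mask_path"] = f"{sid}_{key}.nii"
            else:
                paths[f"{key}_mask_path"] = ""
        rows.append(dict(
            subject_id=sid, group=vol.group or "",
            **paths,
            true_target_volume_mm3=vol.true_target_volume,
            true_icv_volume_mm3=vol.true_icv_volume,
            voxel_dx_mm=vol.voxel_size[0], voxel_dy_mm=vol.voxel_size[1],
            voxel_dz_mm=vol.voxel_size[2],
        ))
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[LabeledVolume]:
    """Read a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    frame = pd.read_csv(manifest_path, keep_default_na=False)
    volumes = []
    for row in frame.itertuples(index=False):
        img = nib.load(str(directory / row.t1_path))
        voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
        masks = {}
        for key in ("target", "icv"):
            p = getattr(row, f"{key}_mask_path")
            masks[key] = (np.asarray(nib.load(str(directory / p)).dataobj,
                                     dtype=np.uint8).astype(bool)
                          if p else None)
        volumes.append(LabeledVolume(
            intensity=np.asarray(img.dataobj, dtype=np.float64),
            voxel_size=voxel,
            target_mask=masks["target"], icv_mask=masks["icv"],
            true_target_volume=float(row.true_target_volume_mm3)
            if row.true_target_volume_mm3 != "" else None,
            true_icv_volume=float(row.true_icv_volume_mm3)
            if row.true_icv_volume_mm3 != "" else None,
            subject_id=row.subject_id, group=row.group or None,
        ))
    return volumes
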