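"""Geometric preparation: landmark-axis alignment and block resampling.

Emulates the standard three-step preparation of small-structure
volumetry: rigidly re-orient the head so the slice (coronal) axis is
parallel to the anterior-posterior landmark axis, resample to the
analysis grid, and extract a fixed block of slices containing the
target.  Intensities are interpolated linearly, label masks with
nearest-neighbour so they stay binary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .phantom import LabeledVolume

__all__ = [
    "LandmarkPair",
    "ResampleSpec",
    "axis_rotation",
    "rotate_points",
    "rotate_volume",
    "align_to_axis",
    "resample_block",
]

_AXIS_NAMES = ("x", "y", "z")


@dataclass(frozen=True)
class LandmarkPair:
    """Anterior/posterior landmark coordinates in volume world space (mm)."""

    anterior_point: tuple[float, float, float]
    posterior_point: tuple[float, float, float]

    def axis_vector(self) -> np.ndarray:
        v = np.subtract(self.posterior_point, self.anterior_point, dtype=float)
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError("degenerate landmarks: points coincide")
        return v / norm

    def validate_inside(self, volume: LabeledVolume) -> None:
        bounds = [(n - 1) * d for n, d in
                  zip(volume.intensity.shape, volume.voxel_size)]
        for name, p in (("anterior_point", self.anterior_point),
                        ("posterior_point", self.posterior_point)):
            for k, (c, b) in enumerate(zip(p, bounds)):
                if not (0.0 <= c <= b):
                    raise ValueError(
                        f"{name} outside volume bounds along axis "
                        f"{_AXIS_NAMES[k]}: {c} not in [0, {b}]")


@dataclass(frozen=True)
class ResampleSpec:
    """Target grid of the analysis block (50 slices of 512x512 at full scale)."""

    in_plane_spacing: float = 0.125
    slice_thickness: float = 0.5
    block_slices: int = 50
    block_plane_size: int = 512

    def validate(self) -> None:
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be > 0")
        if self.block_slices < 1 or self.block_plane_size < 1:
            raise ValueError("block dimensions must be >= 1")


def axis_rotation(landmarks: LandmarkPair) -> np.ndarray:
    """Rotation matrix mapping the landmark axis onto the slice axis (+z)."""
    v = landmarks.axis_vector()
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [v])
    return rot.as_matrix()


def rotate_points(points: np.ndarray, R: np.ndarray,
                  center: np.ndarray) -> np.ndarray:
    """Apply the rotation ``R`` about ``center`` (world mm) to points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - center) @ R.T + center


def _volume_center(volume: LabeledVolume) -> np.ndarray:
    return np.array([(n - 1) / 2.0 * d for n, d in
                     zip(volume.intensity.shape, volume.voxel_size)])


def rotate_volume(volume: LabeledVolume, R: np.ndarray) -> LabeledVolume:
    """Rigidly rotate a volume about its world center.

    Intensity uses linear interpolation, masks nearest-neighbour.  The
    grid (shape and voxel sizes) is unchanged; content leaving the grid
    is filled with the volume's minimum intensity (background).
    """
    S = np.diag(volume.voxel_size)
    Sinv = np.diag([1.0 / d for d in volume.voxel_size])
    center = _volume_center(volume)
    # output voxel index -> input voxel index
    matrix = Sinv @ R.T @ S
    offset = Sinv @ (center - R.T @ center)
    background = float(volume.intensity.min())
    intensity = ndimage.affine_transform(
        volume.intensity, matrix, offset=offset, order=1,
        mode="constant", cval=background)

    def _rot_mask(mask):
        if mask is None:
            return None
        return ndimage.affine_transform(
            mask.astype(np.uint8), matrix, offset=offset, order=0,
            mode="constant", cval=0).astype(bool)

    target = _rot_mask(volume.target_mask)
    icv = _rot_mask(volume.icv_mask)
    vv = volume.voxel_volume
    return LabeledVolume(
        intensity=intensity, voxel_size=volume.voxel_size,
        target_mask=target, icv_mask=icv,
        true_target_volume=None if target is None else float(target.sum()) * vv,
        true_icv_volume=None if icv is None else float(icv.sum()) * vv,
        subject_id=volume.subject_id, group=volume.group)


def align_to_axis(volume: LabeledVolume,
                  landmarks: LandmarkPair) -> LabeledVolume:
    """Rotate the volume so the landmark axis is parallel to the slice axis.

    Rigid (rotation only, about the volume center); mask volumes are
    preserved up to nearest-neighbour interpolation error.  If the
    landmarks are already aligned with the slice axis the grid is
    returned unchanged.
    """
    landmarks.validate_inside(volume)
    v = landmarks.axis_vector()
    angle = np.degrees(np.arccos(np.clip(abs(v[2]), -1.0, 1.0)))
    if angle < 1e-7:
        return dataclasses.replace(volume)
    return rotate_volume(volume, axis_rotation(landmarks))


def resample_block(volume: LabeledVolume, spec: ResampleSpec,
                   block_center=None) -> LabeledVolume:
    """Resample a centered block to the analysis grid.

    The block is ``block_plane_size^2 x block_slices`` voxels at the
    requested spacings, centered on ``block_center`` (world mm).  When
    no center is given, the target-mask centroid is used (the phantom
    analogue of manual slice pre-selection).  Raises ``ValueError``
    naming the axis if the block extends beyond the volume.
    """
    spec.validate()
    if block_center is None:
        if volume.target_mask is None or not volume.target_mask.any():
            raise ValueError("block_center required when no target mask is "
                             "available to center on")
        idx = np.argwhere(volume.target_mask)
        block_center = idx.mean(axis=0) * np.asarray(volume.voxel_size)
    block_center = np.asarray(block_center, dtype=float)

    out_shape = (spec.block_plane_size, spec.block_plane_size, spec.block_slices)
    spacings = (spec.in_plane_spacing, spec.in_plane_spacing,
                spec.slice_thickness)
    coords_1d = []
    for k in range(3):
        n_out, sp, d = out_shape[k], spacings[k], volume.voxel_size[k]
        world = block_center[k] + (np.arange(n_out) - (n_out - 1) / 2.0) * sp
        lo, hi = world[0], world[-1]
        limit = (volume.intensity.shape[k] - 1) * d
        if lo < -1e-9 or hi > limit + 1e-9:
            raise ValueError(
                f"block exceeds volume bounds along axis {_AXIS_NAMES[k]}: "
                f"[{lo:.3f}, {hi:.3f}] mm outside [0, {limit:.3f}]")
        coords_1d.append(world / d)
    grid = np.meshgrid(*coords_1d, indexing="ij")
    coords = np.stack([g.reshape(-1) for g in grid])

    intensity = ndimage.map_coordinates(
        volume.intensity, coords, order=1).reshape(out_shape)

    def _map_mask(mask):
        if mask is None:
            return None
        return ndimage.map_coordinates(
            mask.astype(np.uint8), coords, order=0).reshape(out_shape).astype(bool)

    target = _map_mask(volume.target_mask)
    icv = _map_mask(volume.icv_mask)
    vv = float(np.prod(spacings))
    return LabeledVolume(
        intensity=intensity, voxel_size=spacings,
        target_mask=target, icv_mask=icv,
        true_target_volume=None if target is None else float(target.sum()) * vv,
        true_icv_volume=None if icv is None else float(icv.sum()) * vv,
        subject_id=volume.subject_id, group=volume.group)
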