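"""Contrast-shift data augmentation.

Scan-to-scan contrast variation is the dominant nuisance factor for
intensity-based segmentation of low-contrast structures; the training
set is therefore expanded with globally contrast-shifted copies of each
image so the segmenter becomes robust to it.  The transform family is a
per-image affine intensity map plus an optional gamma, applied to the
min-max-normalized image and rescaled to the input range; label masks
are never touched, and the transform is monotone in intensity wherever
no clipping occurs, so anatomical information is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AugmentSpec", "contrast_shift", "build_augmented_set"]


@dataclass(frozen=True)
class AugmentSpec:
    """Sampling ranges for the per-copy contrast transform.

    ``factor`` is the number of augmented copies per source image; the
    originals are always retained, so the output set has
    ``(factor + 1) x`` the input size.
    """

    factor: int = 6
    gain_range: tuple[float, float] = (0.5, 1.5)
    offset_range: tuple[float, float] = (-0.2, 0.2)
    gamma_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def validate(self) -> None:
        if self.factor < 1:
            raise ValueError("augmentation factor must be >= 1")
        for name in ("gain_range", "offset_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"{name} must be a finite interval")
        if self.gamma_range[0] <= 0:
            raise ValueError("gamma must be > 0")


def contrast_shift(image: np.ndarray, gain: float, offset: float,
                   gamma: float = 1.0) -> np.ndarray:
    """Apply a global contrast transform to one image.

    The image is min-max normalized, mapped through
    ``clip(gain * x**gamma + offset, 0, 1)`` and rescaled to the input
    intensity range.  Identity at gain=1, offset=0, gamma=1.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    img = np.asarray(image, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return img.copy()
    x = (img - lo) / (hi - lo)
    y = np.clip(gain * np.power(x, gamma) + offset, 0.0, 1.0)
    return lo + y * (hi - lo)


def build_augmented_set(images: Sequence, spec: AugmentSpec) -> list:
    """Expand a training set with contrast-shifted copies.

    ``images`` is a sequence of arrays or of ``(image, mask)`` pairs;
    masks are carried through unchanged.  Output order is all originals
    followed by the augmented copies; sampling is reproducible per seed.
    """
    spec.validate()
    items = list(images)
    if not items:
        raise ValueError("augmentation input must be nonempty")
    rng = np.random.default_rng(spec.seed)
    out = list(items)
    for _ in range(spec.factor):
        for item in items:
            gain = rng.uniform(*spec.gain_range)
            offset = rng.uniform(*spec.offset_range)
            gamma = rng.uniform(*spec.gamma_range)
            if isinstance(item, tuple):
                img, mask = item
                out.append((contrast_shift(img, gain, offset, gamma), mask))
            else:
                out.append(contrast_shift(item, gain, offset, gamma))
    return out
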