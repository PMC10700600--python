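"""Overlap metrics, HD95 and Bland-Altman against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from hypovol.metrics import (ConfusionCounts, bland_altman, boundary_voxels,
                             confusion, hd95, overlap_metrics)

# ---------------------------------------------------------------------------
# independent oracles


def confusion_oracle(pred, truth):
    """Triple-loop voxel count."""
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            for k in range(pred.shape[2]):
                p, t = bool(pred[i, j, k]), bool(truth[i, j, k])
                tp += p and t
                fp += p and not t
                fn += t and not p
                tn += not p and not t
    return tp, fp, tn, fn


def boundary_oracle(mask):
    """A foreground voxel is boundary iff any of its 6 face neighbours is
    background or outside the array."""
    out = np.zeros_like(mask, dtype=bool)
    idx = np.argwhere(mask)
    for i, j, k in idx:
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                    and 0 <= nk < mask.shape[2]) or not mask[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def hd95_oracle(a, b, voxel_size):
    """All-pairs distances between boundary sets, directed 95th percentiles."""
    pa = np.argwhere(boundary_oracle(a)).astype(float) * voxel_size
    pb = np.argwhere(boundary_oracle(b)).astype(float) * voxel_size
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(np.percentile(d.min(axis=1), 95),
               np.percentile(d.min(axis=0), 95))


def random_blob(rng, shape, p=0.25):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


# ---------------------------------------------------------------------------


class TestConfusion:
    def test_identical_masks(self, rng):
        m = random_blob(rng, (6, 6, 6))
        c = confusion(m, m)
        assert c.fp == c.fn == 0
        assert c.tp == m.sum()

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = b[3, 3, 3] = True
        assert confusion(a, b).tp == 0

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            p = random_blob(rng, (8, 8, 8))
            t = random_blob(rng, (8, 8, 8))
            c = confusion(p, t)
            assert (c.tp, c.fp, c.tn, c.fn) == confusion_oracle(p, t)
            assert c.total == p.size

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestOverlapMetrics:
    def test_closed_form_counts(self):
        m = overlap_metrics(ConfusionCounts(tp=1, fp=1, tn=0, fn=1))
        assert m.iou == pytest.approx(1 / 3)
        assert m.dice == pytest.approx(1 / 2)
        assert m.precision == pytest.approx(1 / 2)
        assert m.recall == pytest.approx(1 / 2)

    def test_perfect_overlap(self):
        m = overlap_metrics(ConfusionCounts(tp=10, fp=0, tn=5, fn=0))
        assert (m.iou, m.precision, m.recall, m.dice) == (1, 1, 1, 1)

    def test_undefined_flagged_not_zero(self):
        m = overlap_metrics(ConfusionCounts(tp=0, fp=0, tn=8, fn=0))
        assert m.iou is None and m.dice is None
        assert m.precision is None and m.recall is None

    def test_dice_iou_identity(self, rng):
        # dice = 2*iou / (1 + iou), exactly, on integer counts
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 50, 3)
            if tp + fp + fn == 0:
                continue
            m = overlap_metrics(ConfusionCounts(int(tp), int(fp), 0, int(fn)))
            assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-12)


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = random_blob(rng, (6, 6, 6))
        assert hd95(m, m) == 0.0

    def test_single_voxels_anisotropic(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 1] = True
        b[2, 2, 4] = True
        assert hd95(a, b, voxel_size=(1.0, 1.0, 0.5)) == pytest.approx(1.5)

    def test_matches_all_pairs_oracle(self, rng):
        voxel = np.array([0.8, 1.0, 1.25])
        for _ in range(5):
            a = random_blob(rng, (10, 10, 10), p=0.2)
            b = random_blob(rng, (10, 10, 10), p=0.2)
            assert hd95(a, b, voxel) == pytest.approx(
                hd95_oracle(a, b, voxel), rel=1e-9)

    def test_symmetry(self, rng):
        a = random_blob(rng, (9, 9, 9))
        b = random_blob(rng, (9, 9, 9))
        assert hd95(a, b) == hd95(b, a)

    def test_bounded_by_exact_hausdorff(self, rng):
        a = random_blob(rng, (8, 8, 8))
        b = random_blob(rng, (8, 8, 8))
        pa = np.argwhere(boundary_oracle(a)).astype(float)
        pb = np.argwhere(boundary_oracle(b)).astype(float)
        d = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1))
        exact_hd = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert hd95(a, b) <= exact_hd + 1e-9

    def test_singleton_boundaries_equal_exact_hausdorff(self):
        # one boundary point per mask: percentile degenerates to the max
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[2, 3, 2] = True
        b[8, 2, 2] = True
        assert hd95(a, b) == pytest.approx(np.sqrt(36 + 1))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hd95(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), bool))

    def test_boundary_extraction_matches_oracle(self, rng):
        m = random_blob(rng, (7, 7, 7), p=0.4)
        assert np.array_equal(boundary_voxels(m), boundary_oracle(m))


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = bland_altman(x, x)
        assert r.mean_difference == 0
        assert r.loa_lower == r.loa_upper == 0

    def test_constant_offset_zero_variance(self):
        a = np.array([1.0, 2.0, 3.0])
        r = bland_altman(a + 0.5, a)
        assert r.mean_difference == pytest.approx(0.5)
        assert r.sd_difference == 0

    def test_ci_closed_forms(self, rng):
        a = rng.normal(10, 1, 30)
        b = rng.normal(10, 1, 30)
        r = bland_altman(a, b)
        d = a - b
        sd = d.std(ddof=1)
        tq = stats.t.ppf(0.975, 29)
        assert r.mean_difference == pytest.approx(d.mean())
        assert r.loa_upper == pytest.approx(d.mean() + 1.96 * sd)
        assert r.ci_mean[1] - r.ci_mean[0] == pytest.approx(
            2 * tq * sd / np.sqrt(30))
        assert r.ci_loa_lower[1] - r.ci_loa_lower[0] == pytest.approx(
            2 * tq * np.sqrt(3 * sd ** 2 / 30))
        assert r.loa_lower <= r.mean_difference <= r.loa_upper

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])
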