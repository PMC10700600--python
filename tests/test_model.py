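"""Segmenter: loss, architecture, training protocol, volume prediction."""

import dataclasses

import numpy as np
import pytest

from hypovol.model import (EarlyStopping, ModelConfig, TrainConfig,
                           _loss_and_grad, _one_hot, build_model,
                           combined_loss, cross_entropy, load_model,
                           predict_volume, save_model, soft_jaccard, train)
from hypovol.phantom import LabeledVolume


def loss_oracle(probs, onehot):
    """Scalar-loop cross-entropy plus 1 - soft-Jaccard (foreground)."""
    N, C, H, W = probs.shape
    ce = 0.0
    inter = psum = tsum = 0.0
    for n in range(N):
        for i in range(H):
            for j in range(W):
                for c in range(C):
                    p = min(max(probs[n, c, i, j], 1e-7), 1.0)
                    ce -= onehot[n, c, i, j] * np.log(p)
                    if c > 0:
                        inter += probs[n, c, i, j] * onehot[n, c, i, j]
                        psum += probs[n, c, i, j]
                        tsum += onehot[n, c, i, j]
    ce /= N * H * W
    jac = (inter + 1e-7) / (psum + tsum - inter + 1e-7)
    return ce + (1.0 - jac)


class TestCombinedLoss:
    def test_perfect_prediction_near_zero(self):
        labels = (np.random.default_rng(0).random((2, 6, 6)) < 0.4)
        onehot = _one_hot(labels.astype(np.uint8), 2)
        probs = np.clip(onehot, 1e-6, 1 - 1e-6)
        probs /= probs.sum(axis=1, keepdims=True)
        assert combined_loss(probs, onehot) < 1e-3

    def test_uniform_prediction_ce_is_ln2(self, rng):
        labels = (rng.random((3, 5, 5)) < 0.3).astype(np.uint8)
        onehot = _one_hot(labels, 2)
        probs = np.full_like(onehot, 0.5)
        assert cross_entropy(probs, onehot) == pytest.approx(np.log(2))

    def test_matches_scalar_loop_oracle(self, rng):
        z = rng.standard_normal((2, 2, 4, 4))
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        labels = (rng.random((2, 4, 4)) < 0.5).astype(np.uint8)
        onehot = _one_hot(labels, 2)
        assert combined_loss(probs, onehot) == pytest.approx(
            loss_oracle(probs, onehot), rel=1e-6)

    def test_nonnegative_and_jaccard_bounded(self, rng):
        for _ in range(10):
            z = rng.standard_normal((1, 2, 4, 4))
            probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            labels = (rng.random((1, 4, 4)) < 0.5).astype(np.uint8)
            onehot = _one_hot(labels, 2)
            assert combined_loss(probs, onehot) >= 0
            assert 0.0 <= soft_jaccard(probs, onehot) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            combined_loss(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 5, 5)))

    def test_gradient_matches_directional_derivative(self, rng):
        cfg = ModelConfig(encoder_family="vgg-like", depth=2,
                          base_channels=2, input_size=8)
        m = build_model(cfg, seed=1)
        x = rng.standard_normal((2, 8, 8)).astype(np.float32)
        onehot = _one_hot((rng.random((2, 8, 8)) < 0.3).astype(np.uint8), 2)
        l0, dp = _loss_and_grad(m.forward(x), onehot)
        for p in m.params():
            p.grad[...] = 0
        m.backward(dp)
        g2 = sum(float((p.grad ** 2).sum()) for p in m.params())
        eps = 1e-3 / np.sqrt(g2)
        for p in m.params():
            p.value -= (eps * p.grad).astype(np.float32)
        l1, _ = _loss_and_grad(m.forward(x), onehot)
        assert (l1 - l0) / (-eps * g2) == pytest.approx(1.0, abs=0.05)


class TestBuildModel:
    def test_forward_is_softmax_normalized(self):
        cfg = ModelConfig(input_size=16, base_channels=4)
        m = build_model(cfg, seed=0)
        probs = m.forward(np.zeros((2, 16, 16), dtype=np.float32))
        assert probs.shape == (2, 2, 16, 16)
        assert np.all(np.isfinite(probs))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_output_shape_matches_input(self):
        m = build_model(ModelConfig(input_size=64), seed=0)
        probs = m.forward(np.zeros((1, 64, 64), dtype=np.float32))
        assert probs.shape == (1, 2, 64, 64)

    @pytest.mark.parametrize("family", ["vgg-like", "resnet-like",
                                        "inception-like", "efficient-like"])
    def test_all_families_build_and_run(self, family):
        cfg = ModelConfig(encoder_family=family, depth=2, base_channels=4,
                          input_size=16)
        probs = build_model(cfg, seed=3).forward(
            np.zeros((1, 16, 16), dtype=np.float32))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_efficient_like_has_fewest_parameters(self):
        counts = {}
        for family in ("vgg-like", "resnet-like", "inception-like",
                       "efficient-like"):
            cfg = ModelConfig(encoder_family=family, depth=2,
                              base_channels=8, input_size=32)
            counts[family] = build_model(cfg, seed=0).n_parameters
        assert counts["efficient-like"] < counts["vgg-like"]
        assert counts["efficient-like"] < counts["resnet-like"]

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_model(ModelConfig(input_size=50, depth=2))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="encoder_family"):
            build_model(ModelConfig(encoder_family="transformer"))


class TestEarlyStopping:
    def test_increasing_loss_stops_at_patience_exhaustion(self):
        stopper = EarlyStopping(patience=2)
        losses = [0.5, 0.6, 0.7, 0.8]
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert stopped_at == 3
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        decisions = [stopper.update(v) for v in [0.5, 0.6, 0.4, 0.5, 0.6]]
        assert decisions == [False, False, False, False, True]
        assert stopper.best_epoch == 3
        assert stopper.best_value == 0.4


def _tiny_dataset(rng, n=8, size=16):
    """Bright disc on dark background; easily learnable."""
    X = np.zeros((n, size, size), dtype=np.float32)
    Y = np.zeros((n, size, size), dtype=np.uint8)
    for i in range(n):
        cx, cy = rng.integers(5, size - 5, 2)
        ii, jj = np.mgrid[:size, :size]
        disc = (ii - cx) ** 2 + (jj - cy) ** 2 < 9
        X[i] = 0.1 + 0.7 * disc + rng.normal(0, 0.02, (size, size))
        Y[i] = disc
    return X, Y


class TestTrain:
    def test_same_seed_identical_histories(self, rng):
        X, Y = _tiny_dataset(rng)
        cfg = TrainConfig(max_epochs=2, patience=2, seed=5)
        histories = []
        for _ in range(2):
            m = build_model(ModelConfig(input_size=16, base_channels=4),
                            seed=3)
            histories.append(train(m, (X, Y), (X[:2], Y[:2]), cfg))
        assert histories[0].val_loss == histories[1].val_loss
        assert histories[0].train_loss == histories[1].train_loss

    def test_best_epoch_is_argmin_val_loss(self, rng):
        X, Y = _tiny_dataset(rng)
        m = build_model(ModelConfig(input_size=16, base_channels=4), seed=3)
        hist = train(m, (X, Y), (X[:2], Y[:2]),
                     TrainConfig(max_epochs=4, patience=4, seed=5))
        assert hist.best_epoch == int(np.argmin(hist.val_loss)) + 1

    def test_restored_weights_reproduce_best_val_loss(self, rng):
        from hypovol.model import _evaluate

        X, Y = _tiny_dataset(rng)
        m = build_model(ModelConfig(input_size=16, base_channels=4), seed=3)
        hist = train(m, (X, Y), (X[:2], Y[:2]),
                     TrainConfig(max_epochs=4, patience=4, seed=5))
        loss, _ = _evaluate(m, X[:2], Y[:2])
        assert loss == pytest.approx(min(hist.val_loss), abs=1e-6)

    def test_empty_dataset_rejected(self, rng):
        X, Y = _tiny_dataset(rng)
        m = build_model(ModelConfig(input_size=16, base_channels=4), seed=3)
        with pytest.raises(ValueError, match="nonempty"):
            train(m, (X[:0], Y[:0]), (X, Y), TrainConfig())


class TestPredictVolume:
    def test_all_background_flagged_empty(self):
        m = build_model(ModelConfig(input_size=16, base_channels=4), seed=0)
        # bias the head so background wins everywhere
        m.head.b.value[:] = np.array([5.0, -5.0], dtype=np.float32)
        vol = LabeledVolume(intensity=np.zeros((16, 16, 4)),
                            voxel_size=(1, 1, 1))
        res = predict_volume(m, vol)
        assert res.empty
        assert res.mask.shape == (16, 16, 4)
        assert res.ms_per_slice > 0

    def test_prediction_deterministic(self, rng):
        m = build_model(ModelConfig(input_size=16, base_channels=4), seed=0)
        vol = LabeledVolume(intensity=rng.random((16, 16, 4)),
                            voxel_size=(1, 1, 1))
        a, b = predict_volume(m, vol), predict_volume(m, vol)
        assert np.array_equal(a.mask, b.mask)

    def test_grid_mismatch_rejected(self, rng):
        m = build_model(ModelConfig(input_size=16, base_channels=4), seed=0)
        vol = LabeledVolume(intensity=rng.random((20, 20, 4)),
                            voxel_size=(1, 1, 1))
        with pytest.raises(ValueError, match="input size"):
            predict_volume(m, vol)


class TestEndToEndSegmentation:
    def test_trained_model_segments_noiseless_phantom(
            self, trained_target_model, noiseless_volume):
        from hypovol.metrics import confusion, overlap_metrics

        model, _ = trained_target_model
        res = predict_volume(model, noiseless_volume)
        dice = overlap_metrics(
            confusion(res.mask, noiseless_volume.target_mask)).dice
        assert dice >= 0.9

    def test_save_load_round_trip(self, tmp_path, rng):
        m = build_model(ModelConfig(input_size=16, base_channels=4), seed=2)
        save_model(m, tmp_path / "model.npz",
                   train_config=TrainConfig(), seed=2)
        back = load_model(tmp_path / "model.npz")
        x = rng.random((2, 16, 16)).astype(np.float32)
        assert np.array_equal(m.forward(x), back.forward(x))
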