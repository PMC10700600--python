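"""Slice-wise segmentation model and its training protocol.

A 2-D encoder-decoder of "U" topology is trained per-slice with the sum
of categorical cross-entropy and Jaccard loss, Adam (step 1e-3, moment
decays 0.9/0.999), batch size 4, for up to 25 epochs with early
stopping: training halts once the validation loss has not improved for
``patience`` consecutive epochs, and the weights of the lowest
validation-loss epoch are restored for prediction.  Applied to a volume
the model segments each slice independently and stacks the argmax
masks; an all-empty prediction is flagged for quality control.

Everything is seeded (weight init, shuffling) so two runs with the same
configuration produce identical histories and weights.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .nn import Adam, UNet
from .phantom import LabeledVolume

__all__ = [
    "ModelConfig", "TrainConfig", "TrainingHistory", "EarlyStopping",
    "cross_entropy", "soft_jaccard", "combined_loss", "build_model",
    "train", "predict_volume", "PredictionResult", "volumes_to_slices",
    "save_model", "load_model", "hard_iou",
]

_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Architecture parameters of the slice segmenter."""

    encoder_family: str = "efficient-like"
    depth: int = 2
    base_channels: int = 8
    input_size: int = 64
    n_classes: int = 2

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2^depth = {2 ** self.depth}")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters."""

    batch_size: int = 4
    max_epochs: int = 25
    patience: int = 10
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (1 <= self.patience <= self.max_epochs):
            raise ValueError("patience must be in [1, max_epochs]")


@dataclass
class TrainingHistory:
    """Per-epoch curves; epochs are numbered from 1."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


class EarlyStopping:
    """Stop when the monitored value has not improved for `patience` epochs.

    ``update`` is called once per epoch (numbered from 1) and returns
    True when training should halt.  ``best_epoch`` is the argmin epoch.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_value = np.inf
        self.best_epoch = 0
        self.epochs_since_improvement = 0
        self.epoch = 0

    def update(self, value: float) -> bool:
        self.epoch += 1
        if value < self.best_value:
            self.best_value = value
            self.best_epoch = self.epoch
            self.epochs_since_improvement = 0
        else:
            self.epochs_since_improvement += 1
        return self.epochs_since_improvement >= self.patience


# ---------------------------------------------------------------------------
# Loss

def _check_probs(probs: np.ndarray, onehot: np.ndarray) -> None:
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: probabilities {probs.shape} vs "
                         f"target {onehot.shape}")


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Categorical cross-entropy, averaged over pixels (NCHW)."""
    _check_probs(probs, onehot)
    p = np.clip(probs, _EPS, 1.0)
    n_pix = probs.size // probs.shape[1]
    return float(-(onehot * np.log(p)).sum() / n_pix)


def soft_jaccard(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Soft Jaccard index of the foreground classes, pooled over the batch."""
    _check_probs(probs, onehot)
    p = probs[:, 1:]
    t = onehot[:, 1:]
    inter = float((p * t).sum())
    union = float(p.sum() + t.sum()) - inter
    return (inter + _EPS) / (union + _EPS)


def combined_loss(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Sum of categorical cross-entropy and Jaccard loss (1 - soft Jaccard).

    Nonnegative; zero only in the perfect-prediction limit.
    """
    return cross_entropy(probs, onehot) + (1.0 - soft_jaccard(probs, onehot))


def _loss_and_grad(probs: np.ndarray, onehot: np.ndarray):
    """Loss value and its gradient with respect to the probabilities."""
    _check_probs(probs, onehot)
    p = np.clip(probs, _EPS, 1.0)
    n_pix = probs.size // probs.shape[1]
    ce = float(-(onehot * np.log(p)).sum() / n_pix)
    dce = -onehot / p / n_pix

    pf = probs[:, 1:]
    tf = onehot[:, 1:]
    inter = float((pf * tf).sum())
    denom = float(pf.sum() + tf.sum()) - inter
    jac = (inter + _EPS) / (denom + _EPS)
    # d jaccard / d p_fg by the quotient rule
    djac_fg = (tf * (denom + _EPS) - (inter + _EPS) * (1.0 - tf)) \
        / (denom + _EPS) ** 2
    grad = dce.copy()
    grad[:, 1:] -= djac_fg
    return ce + (1.0 - jac), grad


def hard_iou(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """IoU of the binarized foreground, pooled over the given arrays."""
    p = pred_labels > 0
    t = true_labels > 0
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


# ---------------------------------------------------------------------------
# Model construction and training

def build_model(config: ModelConfig, seed: int = 0) -> UNet:
    """Instantiate a randomly initialized (seeded) segmenter."""
    config.validate()
    model = UNet(config.encoder_family, config.depth, config.base_channels,
                 config.n_classes, in_channels=1, seed=seed)
    model.config = config
    return model


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:],
                   dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def _evaluate(model: UNet, X: np.ndarray, Y: np.ndarray,
              batch: int = 32) -> tuple[float, float]:
    losses = []
    weights = []
    inter = union = 0
    for i in range(0, len(X), batch):
        xb, yb = X[i:i + batch], Y[i:i + batch]
        probs = model.forward(xb)
        losses.append(combined_loss(probs, _one_hot(yb, model.n_classes)))
        weights.append(len(xb))
        pred = probs.argmax(axis=1) > 0
        t = yb > 0
        inter += np.logical_and(pred, t).sum()
        union += np.logical_or(pred, t).sum()
    loss = float(np.average(losses, weights=weights))
    iou = 1.0 if union == 0 else float(inter / union)
    return loss, iou


def train(model: UNet, train_data, val_data,
          config: TrainConfig) -> TrainingHistory:
    """Train in place; returns the history with best-epoch weights restored.

    ``train_data``/``val_data`` are ``(images, labels)`` pairs of arrays
    shaped (N, H, W); labels are integer class maps.
    """
    config.validate()
    Xt, Yt = train_data
    Xv, Yv = val_data
    if len(Xt) == 0 or len(Xv) == 0:
        raise ValueError("training and validation sets must be nonempty")
    Xt = np.asarray(Xt, dtype=np.float32)
    Xv = np.asarray(Xv, dtype=np.float32)
    rng = np.random.default_rng(config.seed)
    # Log-prior head-bias init: start the predicted foreground rate at the
    # training-set class frequency so the rare class is not squashed by
    # the dominant background gradient in the first epochs.
    freqs = np.array([(Yt == c).mean() for c in range(model.n_classes)])
    model.head.b.value[:] = np.log(np.clip(freqs, 1e-4, None)
                                   ).astype(np.float32)
    opt = Adam(model.params(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    stopper = EarlyStopping(config.patience)
    history = TrainingHistory()
    best_weights = model.get_weights()
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(Xt))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            probs = model.forward(Xt[sel])
            loss, dprobs = _loss_and_grad(probs,
                                          _one_hot(Yt[sel], model.n_classes))
            opt.zero_grad()
            model.backward(dprobs)
            opt.step()
            epoch_losses.append(loss)
        val_loss, val_iou = _evaluate(model, Xv, Yv)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_iou.append(val_iou)
        improved = val_loss < stopper.best_value
        stop = stopper.update(val_loss)
        if improved:
            best_weights = model.get_weights()
        if stop:
            break
    model.set_weights(best_weights)
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = stopper.epoch
    return history


# ---------------------------------------------------------------------------
# Volume prediction

@dataclass
class PredictionResult:
    """Stacked per-slice argmax mask plus timing and the empty-output flag."""

    mask: np.ndarray            # (H, W, Z) bool
    empty: bool
    ms_per_slice: float


def predict_volume(model: UNet, volume: LabeledVolume,
                   batch: int = 32) -> PredictionResult:
    """Segment a volume slice-by-slice along the third (coronal) axis."""
    cfg: ModelConfig = getattr(model, "config", None)
    H, W, Z = volume.intensity.shape
    if cfg is not None and (H, W) != (cfg.input_size, cfg.input_size):
        raise ValueError(f"volume in-plane grid {(H, W)} does not match the "
                         f"model input size {cfg.input_size}")
    slices = np.ascontiguousarray(
        np.moveaxis(volume.intensity, 2, 0)).astype(np.float32)
    t0 = time.perf_counter()
    masks = []
    for i in range(0, Z, batch):
        probs = model.forward(slices[i:i + batch])
        masks.append(probs.argmax(axis=1) > 0)
    elapsed = time.perf_counter() - t0
    mask = np.moveaxis(np.concatenate(masks, axis=0), 0, 2)
    return PredictionResult(mask=mask, empty=not bool(mask.any()),
                            ms_per_slice=elapsed / Z * 1e3)


def volumes_to_slices(volumes: Sequence[LabeledVolume],
                      task: str = "target") -> tuple[np.ndarray, np.ndarray]:
    """Flatten volumes into per-slice training arrays for one task.

    ``task`` selects which mask provides the labels ("target" or "icv").
    """
    imgs, labs = [], []
    for vol in volumes:
        mask = vol.target_mask if task == "target" else vol.icv_mask
        if mask is None:
            raise ValueError(f"volume {vol.subject_id!r} lacks a {task} mask")
        for z in range(vol.intensity.shape[2]):
            imgs.append(vol.intensity[:, :, z])
            labs.append(mask[:, :, z])
    return (np.asarray(imgs, dtype=np.float32),
            np.asarray(labs, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Serialization: weights in numpy's native .npz plus a JSON sidecar

def save_model(model: UNet, path, train_config: Optional[TrainConfig] = None,
               seed: Optional[int] = None) -> Path:
    path = Path(path)
    weights = model.get_weights()
    np.savez(path, *weights)
    sidecar = {"model_config": asdict(model.config),
               "n_parameters": model.n_parameters}
    if train_config is not None:
        sidecar["train_config"] = asdict(train_config)
    if seed is not None:
        sidecar["seed"] = seed
    path_json = path.with_suffix(".json")
    path_json.write_text(json.dumps(sidecar, indent=2))
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_model(path) -> UNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**sidecar["model_config"])
    model = build_model(config, seed=0)
    with np.load(path) as data:
        weights = [data[k] for k in data.files]
    model.set_weights(weights)
    return model
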