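"""Classifier construction, training, prediction and explanation.

Two kinds of classifier handle live here:

* Architecture audits (``mobilenet_v3_small``, ``resnet18``): exact
  declarative layer tables used for parameter/FLOP/model-size accounting
  (see :mod:`mcgscreen.complexity`).  They are not trainable objects.
* Trainable compact networks on numpy: ``compact_cnn`` (a small strided
  2-D CNN for the 224x224 phase-space images) and ``cnn1d`` (the 1-D
  baseline on raw 224-sample cycles).  Both are deliberately narrow so a
  full train/validate cycle runs in minutes on one CPU core.

Training follows the fixed protocol: AdamW (lr 1e-3, weight decay 1e-4),
step decay (x0.5 every 10 epochs), batch size 32, cross-entropy loss, up
to 40 epochs with best-model saving — the checkpoint with the highest
validation AUC is the one returned.  All randomness flows from the
config seed, so two runs with the same seed and data are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .complexity import (
    ArchitectureAudit,
    cnn1d_baseline,
    count_flops,
    count_parameters,
    mobilenet_v3_small,
    resnet18,
)
from .errors import InvalidInputError, InvalidParameterError
from .metrics import roc_auc

__all__ = [
    "TrainConfig",
    "Prediction",
    "CompactCNN",
    "Cnn1dClassifier",
    "build_classifier",
    "train",
    "predict_proba",
    "grad_cam",
    "count_parameters",
    "count_flops",
]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    scheduler_step: int = 10
    scheduler_gamma: float = 0.5
    batch_size: int = 32
    epochs: int = 40
    seed: int = 42

    def validate(self) -> None:
        if min(self.lr, self.weight_decay, self.scheduler_gamma) <= 0:
            raise InvalidParameterError("lr, weight_decay and gamma must be positive")
        if min(self.batch_size, self.epochs, self.scheduler_step) < 1:
            raise InvalidParameterError("batch_size, epochs, scheduler_step must be >= 1")


@dataclass
class Prediction:
    cycle_id: str
    p_ischemia: float


class CompactCNN:
    """Small 2-D CNN for 224x224 phase-space images.

    Layout: 4x average pool (224 -> 56), two strided 3x3 conv+ReLU
    stages (16 then 32 channels, 56 -> 28 -> 14), global average
    pooling, linear head.  The second ReLU output is the Grad-CAM
    target (the last convolutional stage's feature map).
    """

    name = "compact_cnn"
    input_side = 224

    def __init__(self, num_classes: int = 2, seed: int = 42):
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            [
                nn.AvgPool2d(4),
                nn.Conv2d(3, 16, 3, stride=2, padding=1, rng=rng),
                nn.ReLU(),
                nn.Conv2d(16, 32, 3, stride=2, padding=1, rng=rng),
                nn.ReLU(),
                nn.GlobalAvgPool2d(),
                nn.Linear(32, num_classes, rng=rng),
            ]
        )
        self.gradcam_layer = 4  # index of the ReLU after the last conv

    def parameters(self):
        return self.net.parameters()

    def count_macs(self) -> int:
        macs, side = 0, self.input_side // 4
        for layer in self.net.layers:
            if isinstance(layer, nn.Conv2d):
                macs += layer.macs(side)
                side = layer.out_side(side)
            elif isinstance(layer, nn.Linear):
                macs += layer.n_in * layer.n_out
        return macs

    @staticmethod
    def prepare(images: np.ndarray) -> np.ndarray:
        """Accept (N, 224, 224), (N, 224, 224, 3) or (N, 3, 224, 224)."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = np.repeat(images[:, None], 3, axis=1)
        elif images.ndim == 4 and images.shape[-1] == 3:
            images = images.transpose(0, 3, 1, 2)
        elif images.ndim != 4 or images.shape[1] != 3:
            raise InvalidInputError(f"unrecognized image batch shape {images.shape}")
        return images


class Cnn1dClassifier:
    """The 1-D baseline: four strided conv blocks on the raw 224-sample
    cycle, global average pooling, linear head.  Matches the audited
    ``cnn1d`` layer table parameter-for-parameter."""

    name = "cnn1d"
    input_side = 224

    def __init__(self, num_classes: int = 2, seed: int = 42):
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            [
                nn.Conv1d(1, 16, 7, stride=2, padding=3, rng=rng),
                nn.ReLU(),
                nn.Conv1d(16, 32, 5, stride=2, padding=2, rng=rng),
                nn.ReLU(),
                nn.Conv1d(32, 64, 5, stride=2, padding=2, rng=rng),
                nn.ReLU(),
                nn.Conv1d(64, 128, 3, stride=2, padding=1, rng=rng),
                nn.ReLU(),
                nn.GlobalAvgPool1d(),
                nn.Linear(128, num_classes, rng=rng),
            ]
        )
        self.gradcam_layer = 7

    def parameters(self):
        return self.net.parameters()

    def count_macs(self) -> int:
        macs, length = 0, self.input_side
        for layer in self.net.layers:
            if isinstance(layer, nn.Conv1d):
                out_l = (length + 2 * layer.padding - layer.kernel) // layer.stride + 1
                macs += layer.kernel * layer.in_ch * layer.out_ch * out_l
                length = out_l
            elif isinstance(layer, nn.Linear):
                macs += layer.n_in * layer.n_out
        return macs

    @staticmethod
    def prepare(series: np.ndarray) -> np.ndarray:
        series = np.asarray(series, dtype=np.float64)
        if series.ndim == 2:
            series = series[:, None, :]
        if series.ndim != 3:
            raise InvalidInputError(f"unrecognized series batch shape {series.shape}")
        return series


def build_classifier(arch: str, num_classes: int = 2, seed: int = 42):
    """Return a classifier handle for ``arch``.

    ``mobilenet_v3_small`` and ``resnet18`` return architecture audits
    for complexity accounting; ``compact_cnn`` and ``cnn1d`` return
    trainable numpy networks.
    """
    if num_classes < 2:
        raise InvalidParameterError("num_classes must be >= 2")
    if arch == "mobilenet_v3_small":
        return mobilenet_v3_small(num_classes)
    if arch == "resnet18":
        return resnet18(num_classes)
    if arch == "compact_cnn":
        return CompactCNN(num_classes, seed)
    if arch == "cnn1d":
        return Cnn1dClassifier(num_classes, seed)
    raise InvalidParameterError(f"unknown architecture {arch!r}")


def _forward_logits(model, batch: np.ndarray, record: bool = False) -> np.ndarray:
    return model.net.forward(model.prepare(batch), record=record)


def predict_proba(model, images: np.ndarray) -> np.ndarray:
    """Class-1 (ischemia) probability per image: softmax over the 2 logits."""
    if isinstance(model, ArchitectureAudit):
        raise InvalidInputError("architecture audits are not runnable models")
    images = np.asarray(images)
    out = []
    for start in range(0, images.shape[0], 64):
        logits = _forward_logits(model, images[start : start + 64])
        out.append(nn.softmax(logits)[:, 1])
    return np.concatenate(out) if out else np.empty(0)


def train(model, train_x, train_y, val_x, val_y, config: TrainConfig | None = None):
    """Run the fixed training protocol and return (model, history).

    The model is left holding the checkpoint with the highest validation
    AUC; ``history`` is a list of per-epoch dicts (train_loss, val_auc,
    lr).  Deterministic given ``config.seed``.
    """
    if isinstance(model, ArchitectureAudit):
        raise InvalidInputError("architecture audits are not trainable")
    config = config if config is not None else TrainConfig()
    config.validate()
    train_y = np.asarray(train_y, dtype=int)
    val_y = np.asarray(val_y, dtype=int)
    if np.unique(train_y).size < 2:
        raise InvalidInputError("training set must contain both classes")
    if np.unique(val_y).size < 2:
        raise InvalidInputError("validation set must contain both classes")

    rng = np.random.default_rng(config.seed)
    opt = nn.AdamW(model.net.param_pairs(), lr=config.lr, weight_decay=config.weight_decay)
    history = []
    best_auc, best_state = -np.inf, None
    n = len(train_y)
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.scheduler_gamma ** (epoch // config.scheduler_step)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.net.zero_grad()
            logits = _forward_logits(model, np.asarray(train_x)[idx])
            loss, grad = nn.cross_entropy_with_grad(logits, train_y[idx])
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        val_auc = roc_auc(predict_proba(model, val_x), val_y)
        history.append(
            {"epoch": epoch + 1, "train_loss": float(np.mean(losses)), "val_auc": float(val_auc), "lr": opt.lr}
        )
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.net.state()
    if best_state is not None:
        model.net.load_state(best_state)
    return model, history


def save_model(model, path) -> None:
    """Serialize a trainable model's architecture name and weights (.npz)."""
    if isinstance(model, ArchitectureAudit):
        raise InvalidInputError("architecture audits carry no weights")
    arrays = {f"param_{i}": p for i, p in enumerate(model.net.state())}
    np.savez_compressed(path, arch=np.array(model.name), **arrays)


def load_model(path):
    """Rebuild a trainable model from :func:`save_model` output."""
    data = np.load(path, allow_pickle=False)
    model = build_classifier(str(data["arch"]))
    state = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    model.net.load_state(state)
    return model


def _upsample_nearest(plane: np.ndarray, side: int) -> np.ndarray:
    src = plane.shape[0]
    centers = (np.arange(side) + 0.5) * src / side - 0.5
    idx = np.clip(np.round(centers).astype(int), 0, src - 1)
    return plane[np.ix_(idx, idx)]


def grad_cam(model, image: np.ndarray, target_class: int = 1) -> np.ndarray:
    """Gradient-weighted class activation map for one image.

    Standard recipe: gradients of the target-class logit w.r.t. the last
    convolutional stage's feature map are averaged per channel, used to
    weight the activation channels, summed, rectified, upsampled to
    224x224 by nearest neighbor, and min-max normalized.  A gradient
    that vanishes everywhere yields an all-zero map with a warning.
    """
    if isinstance(model, ArchitectureAudit):
        raise InvalidInputError("architecture audits are not runnable models")
    batch = np.asarray(image)[None] if np.asarray(image).ndim in (2, 3) else np.asarray(image)
    logits = _forward_logits(model, batch, record=True)
    seed_grad = np.zeros_like(logits)
    seed_grad[0, target_class] = 1.0
    model.net.zero_grad()
    model.net.backward(seed_grad, record=True)
    acts = model.net._acts[model.gradcam_layer][0]  # (C, h, w)
    grads = model.net._out_grads[model.gradcam_layer][0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    cam = _upsample_nearest(cam, 224)
    if cam.max() <= 0:
        warnings.warn("Grad-CAM gradient vanished; returning an all-zero heatmap")
        return np.zeros((224, 224))
    return (cam - cam.min()) / (cam.max() - cam.min())
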