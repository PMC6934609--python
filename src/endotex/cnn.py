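"""The bespoke frame-classification CNN and the transfer-learning scaffold.

Scratch architecture: five 3x3 convolutional layers with 64, 128, 256, 512
and 512 filters, each followed by ReLU and 2x2 max pooling; then a
1024-unit fully connected layer with ReLU and dropout (p=0.5) and a
3-class softmax output.  Trained by minimizing mean cross-entropy with
Adam at learning rate 0.001.

Transfer scaffold: a VGG16-style conv stack whose first ``n`` conv layers
can be frozen (excluded from gradient updates), a fresh 3-class head, and
optionally a linear SVM fitted on the penultimate feature layer in place
of the softmax head.  Pretrained weights may be supplied as an .npz file;
otherwise layers are randomly initialized (useful for structural tests —
no weights are downloaded).

Frames are grayscale; they are resized to a square network input (any
multiple of 32, so five pooling stages divide evenly) and scaled to
zero-centered floats.  For ImageNet-shaped backbones the single channel is
replicated to three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize
from sklearn.svm import LinearSVC

from . import nn
from .synth import CLASSES, Frame

VGG16_CONV_BLOCKS: tuple[tuple[int, ...], ...] = (
    (64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512),
)
VGG16_N_CONV_LAYERS = sum(len(b) for b in VGG16_CONV_BLOCKS)  # 13


@dataclass(frozen=True)
class ArchitectureSpec:
    """The scratch network's shape; defaults are the canonical architecture."""

    conv_filters: tuple[int, ...] = (64, 128, 256, 512, 512)
    fc_units: int = 1024
    dropout_p: float = 0.5
    n_classes: int = 3


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: cross-entropy loss, Adam at lr 0.001."""

    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    early_stopping_patience: int = 10
    seed: int = 0
    input_size: int = 288
    #: optional early exit once validation accuracy reaches this level
    target_val_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 2^5 = 32")


@dataclass(frozen=True)
class TransferSpec:
    backbone: str = "vgg16"
    n_frozen_conv_layers: int = 3
    head: str = "dense_softmax"  # or "svm_on_last_features"
    pretrained_weights: str | None = None
    n_classes: int = 3


def frames_to_tensor(frames: Sequence[Frame], input_size: int,
                     n_channels: int = 1) -> np.ndarray:
    """Resize frames to (input_size, input_size), scale to [-1, 1] floats."""
    out = np.empty((len(frames), n_channels, input_size, input_size),
                   dtype=np.float32)
    for i, fr in enumerate(frames):
        img = resize(fr.pixels, (input_size, input_size), anti_aliasing=True)
        chan = (img.astype(np.float32) - 0.5) * 2.0
        out[i] = chan  # broadcast over replicated channels
    return out


def labels_to_indices(labels: Sequence[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.array([lut[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label outside the known classes: {exc}") from exc


def build_scratch_model(spec: ArchitectureSpec = ArchitectureSpec(),
                        input_size: int = 288, seed: int = 0) -> nn.Sequential:
    """Instantiate the scratch network for a given square input size."""
    n_stages = len(spec.conv_filters)
    if input_size % (2 ** n_stages) != 0:
        raise ValueError(
            f"input_size must be divisible by 2^{n_stages} "
            f"(= {2 ** n_stages}); got {input_size}")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for f in spec.conv_filters:
        layers += [nn.Conv2D(in_ch, f, rng), nn.ReLU(), nn.MaxPool2x2()]
        in_ch = f
    spatial = input_size // (2 ** n_stages)
    flat = in_ch * spatial * spatial
    layers += [nn.Flatten(), nn.Dense(flat, spec.fc_units, rng), nn.ReLU(),
               nn.Dropout(spec.dropout_p)]
    feature_index = len(layers)  # features = post-ReLU fc activations
    layers += [nn.Dense(spec.fc_units, spec.n_classes, rng)]
    return nn.Sequential(layers, feature_index=feature_index)


def build_transfer_model(spec: TransferSpec = TransferSpec(),
                         input_size: int = 32, seed: int = 0) -> nn.Sequential:
    """VGG16-style backbone with a fresh 3-class head and frozen early convs.

    Only the VGG16 conv stack is provided (13 conv layers, the layout the
    freezing sweep is defined on).  With no weights file, layers are
    randomly initialized.
    """
    if spec.backbone.lower() != "vgg16":
        raise NotImplementedError(
            f"backbone {spec.backbone!r} is not available; only the VGG16 "
            "conv stack is implemented")
    if not (0 <= spec.n_frozen_conv_layers <= VGG16_N_CONV_LAYERS):
        raise ValueError(
            f"n_frozen_conv_layers must be in [0, {VGG16_N_CONV_LAYERS}]")
    if input_size % 32 != 0:
        raise ValueError("input_size must be divisible by 32")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 3  # grayscale replicated to 3 channels
    for block in VGG16_CONV_BLOCKS:
        for f in block:
            layers += [nn.Conv2D(in_ch, f, rng), nn.ReLU()]
            in_ch = f
        layers += [nn.MaxPool2x2()]
    spatial = input_size // 32
    flat = 512 * spatial * spatial
    layers += [nn.Flatten(),
               nn.Dense(flat, 4096, rng), nn.ReLU(), nn.Dropout(0.5),
               nn.Dense(4096, 4096, rng), nn.ReLU(), nn.Dropout(0.5)]
    feature_index = len(layers)
    layers += [nn.Dense(4096, spec.n_classes, rng)]  # replaced 1000-way head
    net = nn.Sequential(layers, feature_index=feature_index)
    if spec.pretrained_weights is not None:
        load_weights(net, spec.pretrained_weights)
    for conv in net.conv_layers()[: spec.n_frozen_conv_layers]:
        conv.frozen = True
    return net


def save_weights(net: nn.Sequential, path: str | Path) -> None:
    arrays = {}
    for i, layer in enumerate(net.layers):
        for k, v in layer.params().items():
            arrays[f"layer{i}.{k}"] = v
    np.savez(path, **arrays)


def load_weights(net: nn.Sequential, path: str | Path) -> None:
    with np.load(path) as data:
        for i, layer in enumerate(net.layers):
            for k, v in layer.params().items():
                v[...] = data[f"layer{i}.{k}"]


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def _eval_loss_acc(net: nn.Sequential, x: np.ndarray, y: np.ndarray,
                   batch_size: int) -> tuple[float, float]:
    logits = net.predict_logits(x, batch_size)
    loss, _ = nn.cross_entropy_with_grad(logits, y)
    acc = float(np.mean(logits.argmax(axis=1) == y))
    return loss, acc


def train_model(net: nn.Sequential,
                x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray,
                cfg: TrainConfig = TrainConfig()) -> TrainHistory:
    """Minimize mean cross-entropy with Adam; keep best-validation weights.

    Deterministic given ``cfg.seed`` (shuffling, dropout).  Early stopping
    on validation loss with ``cfg.early_stopping_patience``; optionally
    stops once validation accuracy reaches ``cfg.target_val_accuracy``.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(cfg.seed)
    net.set_rng(rng)
    opt = nn.Adam(net, lr=cfg.learning_rate)
    history = TrainHistory()
    best_loss = np.inf
    best_state = net.get_state()
    stale = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            logits = net.forward(x_train[idx], train=True)
            loss, grad = nn.cross_entropy_with_grad(logits, y_train[idx])
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_loss, val_acc = _eval_loss_acc(net, x_val, y_val, cfg.batch_size)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = net.get_state()
            stale = 0
        else:
            stale += 1
        if (cfg.target_val_accuracy is not None
                and val_acc >= cfg.target_val_accuracy):
            break
        if stale > cfg.early_stopping_patience:
            break
    net.set_state(best_state)
    return history


@dataclass
class CNNClassifier:
    """A trained network plus the preprocessing needed to call it on frames."""

    net: nn.Sequential
    input_size: int
    n_channels: int = 1
    history: TrainHistory | None = None

    def predict(self, frames: Sequence[Frame]) -> np.ndarray:
        x = frames_to_tensor(frames, self.input_size, self.n_channels)
        probs = self.net.predict_proba(x)
        return np.array([CLASSES[i] for i in probs.argmax(axis=1)])

    def predict_proba(self, frames: Sequence[Frame]) -> np.ndarray:
        x = frames_to_tensor(frames, self.input_size, self.n_channels)
        return self.net.predict_proba(x)


@dataclass
class SVMHeadClassifier:
    """A frozen feature extractor with a linear-SVM decision head."""

    net: nn.Sequential
    svc: LinearSVC
    input_size: int
    n_channels: int = 1

    def predict(self, frames: Sequence[Frame]) -> np.ndarray:
        x = frames_to_tensor(frames, self.input_size, self.n_channels)
        return self.svc.predict(self.net.features(x))


def svm_on_features(net: nn.Sequential, x: np.ndarray,
                    labels: Sequence[str], C: float = 1.0,
                    seed: int = 0) -> LinearSVC:
    """Fit a linear SVM on the network's last feature layer activations.

    Features are extracted in eval mode (dropout off), so repeated
    featurization of the same input is identical.
    """
    if len(x) == 0:
        raise ValueError("cannot extract features from empty input")
    feats = net.features(x)
    svc = LinearSVC(C=C, loss="hinge", multi_class="ovr",
                    random_state=seed, max_iter=4000, tol=1e-2)
    svc.fit(feats, np.asarray(labels))
    return svc
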