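"""The residual classifier: build, count, train, predict, save/load.

The pinned default — five residual blocks of 128 channels (3x3, same
padding), a 1x1 projection only where channel counts change (block 1),
dropout after each residual addition, 2x2 max pooling per block, adaptive
average pooling to 2x2, a 128-d linear latent layer, and a 2-class softmax
head — totals 659,074 trainable parameters, i.e. 0.66 million to two
decimals.  The architecture is size-agnostic thanks to the adaptive pool,
so small images and narrow channel lists make cheap test-scale variants.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .errors import DataError, ParameterError
from .phantoms import LABELS, LabeledImage


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    block_channels: tuple[int, ...] = (128, 128, 128, 128, 128)
    kernel_size: int = 3
    dropout_rate: float = 0.1  # train-time; inference rate set by calibration
    pool_output: int = 2
    latent_dim: int = 128
    num_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.block_channels) < 1:
            raise ParameterError("block_channels must contain at least one entry")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.pool_output < 1:
            raise ParameterError("pool_output must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ParameterError("kernel_size must be odd")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    optimizer: str = "adam"
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")


class TrustNet:
    """Network state: architecture config plus all layer parameters.

    ``trained`` flips to True after :func:`train_network`; stochastic
    inference refuses to run on an untrained state.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.trained = False
        rng = np.random.default_rng(seed)
        self.blocks: list[_nn.ResidualBlock] = []
        in_ch = config.in_channels
        for out_ch in config.block_channels:
            self.blocks.append(_nn.ResidualBlock(in_ch, out_ch, config.kernel_size, rng))
            in_ch = out_ch
        self.avgpool = _nn.AdaptiveAvgPool2d(config.pool_output)
        flat = config.block_channels[-1] * config.pool_output**2
        self.fc_latent = _nn.Linear(flat, config.latent_dim, rng)
        self.fc_head = _nn.Linear(config.latent_dim, config.num_classes, rng)

    # ---- plumbing -------------------------------------------------------
    def layers(self) -> list[_nn.Layer]:
        out: list[_nn.Layer] = []
        for b in self.blocks:
            out.extend(b.layers())
        out.extend([self.avgpool, self.fc_latent, self.fc_head])
        return out

    def parameters(self) -> list[tuple[_nn.Layer, str]]:
        return [(layer, name) for layer in self.layers() for name in layer.params]

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    def min_input_size(self) -> int:
        return 2 ** len(self.blocks)

    # ---- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, *, training: bool = False,
                dropout_rate: float | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return logits for a batch (B, C, H, W).

        ``dropout_rate`` overrides the config rate (used for MC-dropout
        inference); dropout is applied whenever the rate is positive and an
        rng is supplied, regardless of ``training`` — batch norm follows
        ``training`` alone.
        """
        if x.ndim != 4:
            raise ParameterError(f"expected (B, C, H, W) input, got shape {x.shape}")
        if min(x.shape[2], x.shape[3]) < self.min_input_size():
            raise ParameterError(
                f"input side {min(x.shape[2], x.shape[3])} too small for "
                f"{len(self.blocks)} pooling stages (need >= {self.min_input_size()})"
            )
        rate = self.config.dropout_rate if dropout_rate is None else dropout_rate
        if not training and rng is None:
            rate = 0.0
        h = x
        for b in self.blocks:
            h = b.forward(h, training=training, dropout_rate=rate, rng=rng)
        h = self.avgpool.forward(h)
        h = h.reshape(h.shape[0], -1)
        self._flat_shape = h.shape
        h = self.fc_latent.forward(h)  # linear activation: raw latent kept
        return self.fc_head.forward(h)

    def backward(self, dlogits: np.ndarray, *, capture_target_grad: bool = False) -> None:
        """Backpropagate d(loss)/d(logits); optionally capture the gradient
        at the last block's convolution output (the Grad-CAM target)."""
        d = self.fc_head.backward(dlogits)
        d = self.fc_latent.backward(d)
        s = self.config.pool_output
        d = d.reshape(d.shape[0], self.config.block_channels[-1], s, s)
        d = self.avgpool.backward(d)
        for i, b in enumerate(reversed(self.blocks)):
            d = b.backward(d, capture_conv_grad=(capture_target_grad and i == 0))

    # ---- state dict -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers()):
            for name, value in layer.params.items():
                out[f"layer{i}/{name}"] = value
            if isinstance(layer, _nn.BatchNorm2d):
                out[f"layer{i}/running_mean"] = layer.running_mean
                out[f"layer{i}/running_var"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for name in layer.params:
                layer.params[name] = arrays[f"layer{i}/{name}"].copy()
            if isinstance(layer, _nn.BatchNorm2d):
                layer.running_mean = arrays[f"layer{i}/running_mean"].copy()
                layer.running_var = arrays[f"layer{i}/running_var"].copy()


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> TrustNet:
    """Instantiate an untrained network with seeded He-uniform weights."""
    return TrustNet(config or NetworkConfig(), seed=seed)


def count_parameters(state: TrustNet) -> int:
    """Trainable parameters: conv/linear weights and biases plus batch-norm
    scale/shift; running statistics are excluded."""
    return sum(layer.n_params() for layer in state.layers())


def _as_batch(images: Sequence[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([img.pixels for img in images])[:, None, :, :]
    y = np.array([LABELS.index(img.label) for img in images])
    return x, y


def _validate_pixels(x: np.ndarray) -> None:
    if x.min() < 0 or x.max() > 1:
        raise ParameterError("image values must lie in [0, 1]")


def predict_deterministic(state: TrustNet, image: LabeledImage | np.ndarray) -> np.ndarray:
    """Softmax probabilities with dropout off and batch norm in inference
    mode; repeated calls are identical."""
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    _validate_pixels(pixels)
    logits = state.forward(pixels[None, None, :, :], training=False)
    return _nn.softmax(logits)[0]


def predict_logits_batch(state: TrustNet, images: Sequence[LabeledImage]) -> np.ndarray:
    """Deterministic pre-softmax logits for a batch (temperature scaling)."""
    x, _ = _as_batch(images)
    _validate_pixels(x)
    return state.forward(x, training=False)


def predict_proba_batch(state: TrustNet, images: Sequence[LabeledImage]) -> np.ndarray:
    return _nn.softmax(predict_logits_batch(state, images))


class _Adam:
    def __init__(self, model: TrustNet, lr: float):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in model.layers()}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in model.layers()}

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for layer in self.model.layers():
            for k, g in layer.grads.items():
                m = self.m[id(layer)][k]
                v = self.v[id(layer)][k]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                layer.params[k] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def train_network(
    state: TrustNet,
    train_images: Sequence[LabeledImage],
    val_images: Sequence[LabeledImage],
    tc: TrainingConfig | None = None,
) -> tuple[TrustNet, pd.DataFrame]:
    """Train with cross-entropy + Adam; keep the best-validation-loss
    weights; early-stop after ``patience`` epochs without improvement.
    Fully deterministic given ``tc.seed`` and the initial weights."""
    tc = tc or TrainingConfig()
    if len(train_images) == 0 or len(val_images) == 0:
        raise DataError("train and validation splits must be non-empty")
    train_labels = {img.label for img in train_images}
    if len(train_labels) < 2:
        raise DataError(f"training set contains a single label {train_labels}")
    if tc.optimizer.lower() != "adam":
        raise ParameterError(f"unsupported optimizer {tc.optimizer!r}")

    x_train, y_train = _as_batch(train_images)
    x_val, y_val = _as_batch(val_images)
    rng = np.random.default_rng(tc.seed)
    opt = _Adam(state, tc.learning_rate)

    best_loss = np.inf
    best_state: dict[str, np.ndarray] | None = None
    best_epoch = -1
    history = []
    n = len(train_images)
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = state.forward(xb, training=True, rng=rng)
            probs = _nn.softmax(logits)
            loss = _nn.cross_entropy(probs, yb)
            epoch_loss += loss * len(idx)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            state.zero_grad()
            state.backward(dlogits)
            opt.step()
        val_logits = state.forward(x_val, training=False)
        val_probs = _nn.softmax(val_logits)
        val_loss = _nn.cross_entropy(val_probs, y_val)
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "train_acc": epoch_correct / n,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_state = {k: v.copy() for k, v in state.state_arrays().items()}
            best_epoch = epoch
        elif epoch - best_epoch >= tc.patience:
            break
    if best_state is not None:
        state.load_state_arrays(best_state)
    state.trained = True
    return state, pd.DataFrame(history)


# ---- checkpoint I/O -----------------------------------------------------

def save_checkpoint(state: TrustNet, path: str | Path) -> Path:
    """Single-file archive: config JSON + weight arrays (lossless)."""
    path = Path(path)
    meta = {
        "config": {
            "in_channels": state.config.in_channels,
            "block_channels": list(state.config.block_channels),
            "kernel_size": state.config.kernel_size,
            "dropout_rate": state.config.dropout_rate,
            "pool_output": state.config.pool_output,
            "latent_dim": state.config.latent_dim,
            "num_classes": state.config.num_classes,
        },
        "seed": state.seed,
        "trained": state.trained,
    }
    buf = io.BytesIO()
    np.savez(buf, **state.state_arrays())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        zf.writestr("weights.npz", buf.getvalue())
    return path


def load_checkpoint(path: str | Path) -> TrustNet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        arrays = dict(np.load(io.BytesIO(zf.read("weights.npz"))))
    cfg = meta["config"]
    config = NetworkConfig(
        in_channels=cfg["in_channels"],
        block_channels=tuple(cfg["block_channels"]),
        kernel_size=cfg["kernel_size"],
        dropout_rate=cfg["dropout_rate"],
        pool_output=cfg["pool_output"],
        latent_dim=cfg["latent_dim"],
        num_classes=cfg["num_classes"],
    )
    state = TrustNet(config, seed=meta["seed"])
    state.load_state_arrays(arrays)
    state.trained = bool(meta["trained"])
    return state
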