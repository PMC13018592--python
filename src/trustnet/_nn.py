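"""Minimal NumPy CNN engine: layers with explicit forward/backward passes.

Implements exactly what the residual classifier needs — 2-D convolution via
im2col, batch normalization, ReLU, inverted dropout, 2x2 max pooling,
adaptive average pooling, and fully connected layers — each with a backward
pass so the same code path serves gradient-descent training and
gradient-based saliency (Grad-CAM).

Conventions: activations are float64 arrays shaped (B, C, H, W); parameters
live in ``layer.params`` and their gradients accumulate in ``layer.grads``
during ``backward``.  A layer's backward must follow its own most recent
forward (caches are overwritten per call).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer; subclasses fill params/grads dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: dict = {}

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Conv2d(Layer):
    """Same-padded stride-1 convolution (im2col + matmul)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.params["W"] = _he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.params["b"] = np.zeros(out_ch)
        self.zero_grad()

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        k, p = self.kernel, self.kernel // 2
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H, W, k, k) windows -> (B, H*W, C*k*k) columns
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)
        Wm = self.params["W"].reshape(self.out_ch, -1)
        y = cols @ Wm.T + self.params["b"]
        self._cache = {"cols": cols, "shape": (B, C, H, W)}
        return y.transpose(0, 2, 1).reshape(B, self.out_ch, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols = self._cache["cols"]
        B, C, H, W = self._cache["shape"]
        k, p = self.kernel, self.kernel // 2
        dyf = dy.reshape(B, self.out_ch, H * W).transpose(0, 2, 1)  # (B, HW, Cout)
        Wm = self.params["W"].reshape(self.out_ch, -1)
        self.grads["W"] += (
            np.einsum("bno,bni->oi", dyf, cols).reshape(self.params["W"].shape)
        )
        self.grads["b"] += dyf.sum(axis=(0, 1))
        dcols = dyf @ Wm  # (B, HW, C*k*k)
        dcols = dcols.reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        # Running statistics are state, not trainable parameters.
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grad()

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = {"xhat": xhat, "inv": inv, "training": training, "n": x.shape[0] * x.shape[2] * x.shape[3]}
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache["xhat"], self._cache["inv"]
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        if not self._cache["training"]:
            return dxhat * inv[None, :, None, None]
        n = self._cache["n"]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - s1 / n - xhat * s2 / n) * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        self._cache = {"mask": x > 0}
        return np.where(self._cache["mask"], x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._cache["mask"]


class Dropout(Layer):
    """Inverted dropout; the rate is supplied per call so the training rate
    and the Monte-Carlo inference rate can differ."""

    def forward(self, x: np.ndarray, *, training: bool = False,
                rate: float = 0.0, rng: np.random.Generator | None = None) -> np.ndarray:
        if rate <= 0.0 or rng is None:
            self._cache = {"mask": None}
            return x
        mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
        self._cache = {"mask": mask}
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._cache["mask"]
        return dy if mask is None else dy * mask


class MaxPool2d(Layer):
    """2x2 stride-2 pooling; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        Hc, Wc = H // 2, W // 2
        xt = x[:, :, :2 * Hc, :2 * Wc].reshape(B, C, Hc, 2, Wc, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Hc, Wc, 4)
        idx = xt.argmax(axis=-1)
        self._cache = {"idx": idx, "in_shape": (B, C, H, W)}
        return np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx = self._cache["idx"]
        B, C, H, W = self._cache["in_shape"]
        Hc, Wc = H // 2, W // 2
        dxt = np.zeros((B, C, Hc, Wc, 4))
        np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=-1)
        dxt = dxt.reshape(B, C, Hc, Wc, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((B, C, H, W))
        dx[:, :, :2 * Hc, :2 * Wc] = dxt.reshape(B, C, 2 * Hc, 2 * Wc)
        return dx


class AdaptiveAvgPool2d(Layer):
    """Averages over bins chosen torch-style: bin i spans
    [floor(i*H/S), ceil((i+1)*H/S))."""

    def __init__(self, out_size: int):
        super().__init__()
        self.out_size = out_size

    @staticmethod
    def _bins(n: int, s: int) -> list[tuple[int, int]]:
        return [(int(np.floor(i * n / s)), int(np.ceil((i + 1) * n / s))) for i in range(s)]

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        s = self.out_size
        hb, wb = self._bins(H, s), self._bins(W, s)
        y = np.empty((B, C, s, s))
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                y[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        self._cache = {"in_shape": (B, C, H, W), "hb": hb, "wb": wb}
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._cache["in_shape"]
        hb, wb = self._cache["hb"], self._cache["wb"]
        dx = np.zeros((B, C, H, W))
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += dy[:, :, i, j][:, :, None, None] / area
        return dx


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _he_uniform(rng, (d_out, d_in), d_in)
        self.params["b"] = np.zeros(d_out)
        self.zero_grad()

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        self._cache = {"x": x}
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache["x"]
        self.grads["W"] += dy.T @ x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood; targets are integer class indices."""
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(targets)), targets] + eps)))


class ResidualBlock:
    """conv3x3 -> BN -> ReLU -> (+ skip, 1x1 projection iff channels differ)
    -> dropout -> 2x2 max pool.  No activation after the addition."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()
        self.proj = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None
        self.dropout = Dropout()
        self.pool = MaxPool2d()

    def layers(self) -> list[Layer]:
        out = [self.conv, self.bn, self.relu, self.dropout, self.pool]
        if self.proj is not None:
            out.insert(3, self.proj)
        return out

    def forward(self, x: np.ndarray, *, training: bool, dropout_rate: float,
                rng: np.random.Generator | None) -> np.ndarray:
        h = self.conv.forward(x, training=training)
        self.conv_out = h  # Grad-CAM target when this is the last block
        h = self.bn.forward(h, training=training)
        h = self.relu.forward(h)
        s = x if self.proj is None else self.proj.forward(x, training=training)
        y = h + s
        y = self.dropout.forward(y, training=training, rate=dropout_rate, rng=rng)
        return self.pool.forward(y)

    def backward(self, dy: np.ndarray, *, capture_conv_grad: bool = False) -> np.ndarray:
        d = self.pool.backward(dy)
        d = self.dropout.backward(d)
        dh, ds = d, d
        dh = self.relu.backward(dh)
        dh = self.bn.backward(dh)
        if capture_conv_grad:
            self.conv_grad = dh.copy()
        dx = self.conv.backward(dh)
        dx += ds if self.proj is None else self.proj.backward(ds)
        return dx
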