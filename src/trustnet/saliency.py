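"""Saliency maps (Grad-CAM, Grad-CAM++, Score-CAM), MSI, and the flip rule.

The target layer is the last residual block's convolution output — standard
practice for CAM methods on small CNNs.  Maps are upsampled bilinearly to
the input size and min-max normalized to [0, 1]; a constant raw map
normalizes to all-zeros by convention (its MSI is 0).

Mean Saliency Intensity (MSI) is the plain mean of the normalized map:
diffuse, indiscriminate attention gives high MSI and correlates with
misclassification, focal attention gives low-to-moderate MSI.  The
correction threshold D = min(max MSI over true positives, max MSI over true
negatives) is fitted on validation outcomes; retained predictions with
MSI > D get their binary label flipped (equality keeps the prediction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skimage.transform import resize

from . import _nn
from .errors import CalibrationError, DataError, ParameterError, StateError
from .network import TrustNet, _validate_pixels
from .phantoms import LABELS, LabeledImage
from .uncertainty import _pass_rng

METHODS = ("gradcam", "gradcam_pp", "scorecam")
MODES = ("deterministic", "mcd")


@dataclass
class SaliencyMap:
    values: np.ndarray
    method: str
    mode: str
    target_layer: str
    explained_class: str


@dataclass
class MSIThreshold:
    D: float
    max_msi_tp: float
    max_msi_tn: float
    source: str = ""


def normalize_map(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant maps become all-zeros."""
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def gradcam_raw(activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Grad-CAM at activation resolution: channel weights are the spatial
    mean of the class-score gradient; map = ReLU(weighted channel sum)."""
    weights = gradients.mean(axis=(1, 2))
    return np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)


def gradcam_pp_raw(activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Grad-CAM++ weighting from second/third-order gradient terms."""
    g2 = gradients**2
    g3 = g2 * gradients
    denom = 2.0 * g2 + (activations * g3).sum(axis=(1, 2), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    weights = (alpha * np.maximum(gradients, 0.0)).sum(axis=(1, 2))
    return np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)


def _forward_with_target(
    state: TrustNet, x: np.ndarray, *, dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    logits = state.forward(x, training=False, dropout_rate=dropout_rate, rng=rng)
    return logits


def _class_grad_pass(
    state: TrustNet, pixels: np.ndarray, class_index: int, *,
    dropout_rate: float = 0.0, rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One forward+backward pass; returns (activations, gradients) of the
    target layer for the given class score, both shaped (C, h, w)."""
    x = pixels[None, None, :, :]
    logits = _forward_with_target(state, x, dropout_rate=dropout_rate, rng=rng)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_index] = 1.0
    state.zero_grad()
    state.backward(dlogits, capture_target_grad=True)
    last = state.blocks[-1]
    return last.conv_out[0], last.conv_grad[0]


def _scorecam_raw(
    state: TrustNet, pixels: np.ndarray, class_index: int, *,
    dropout_rate: float = 0.0, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Score-CAM: channel weight = class-score increase over a blank
    baseline when the input is masked by the normalized activation map."""
    x = pixels[None, None, :, :]
    _forward_with_target(state, x, dropout_rate=dropout_rate, rng=rng)
    acts = state.blocks[-1].conv_out[0]  # (C, h, w)
    size = pixels.shape
    baseline_logits = state.forward(np.zeros((1, 1, *size)), training=False)
    baseline = _nn.softmax(baseline_logits)[0, class_index]
    weights = np.zeros(acts.shape[0])
    masked = []
    kept = []
    for k in range(acts.shape[0]):
        a = acts[k]
        if a.max() - a.min() <= 0:
            continue
        mask = resize(normalize_map(a), size, order=1, anti_aliasing=False,
                      preserve_range=True)
        masked.append((pixels * mask)[None, :, :])
        kept.append(k)
    if masked:
        batch = np.stack(masked)
        probs = _nn.softmax(state.forward(batch, training=False))[:, class_index]
        for k, score in zip(kept, probs):
            weights[k] = score - baseline
    return np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)


def _single_map(
    state: TrustNet, pixels: np.ndarray, class_index: int, method: str, *,
    dropout_rate: float = 0.0, rng: np.random.Generator | None = None,
) -> np.ndarray:
    if method == "scorecam":
        raw = _scorecam_raw(state, pixels, class_index,
                            dropout_rate=dropout_rate, rng=rng)
    else:
        acts, grads = _class_grad_pass(state, pixels, class_index,
                                       dropout_rate=dropout_rate, rng=rng)
        raw = gradcam_raw(acts, grads) if method == "gradcam" else gradcam_pp_raw(acts, grads)
    up = resize(raw, pixels.shape, order=1, anti_aliasing=False, preserve_range=True)
    return normalize_map(up)


def saliency_map(
    state: TrustNet,
    image: LabeledImage | np.ndarray,
    explained_class: str | None = None,
    method: str = "gradcam",
    mode: str = "deterministic",
    p: float = 0.0,
    n_passes: int = 1,
    seed: int = 0,
    image_index: int = 0,
) -> SaliencyMap:
    """Saliency heatmap in [0, 1] for the explained class (default: the
    model's own prediction).

    mode='mcd' runs ``n_passes`` stochastic passes with dropout rate ``p``,
    normalizes each per-pass map, averages, and renormalizes; with p=0 this
    reduces bit-exactly to the deterministic map.
    """
    if not state.trained:
        raise StateError("saliency requires a trained network")
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; choose from {MODES}")
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    _validate_pixels(pixels)
    if explained_class is None:
        from .network import predict_deterministic
        explained_class = LABELS[int(np.argmax(predict_deterministic(state, pixels)))]
    class_index = LABELS.index(explained_class)

    if mode == "deterministic":
        values = _single_map(state, pixels, class_index, method)
    else:
        if n_passes < 1:
            raise ParameterError("n_passes must be >= 1 in mcd mode")
        if p == 0.0:
            # All passes are identical; return the deterministic map
            # bit-exactly rather than averaging equal copies.
            values = _single_map(state, pixels, class_index, method)
        else:
            acc = np.zeros_like(pixels, dtype=float)
            for n in range(n_passes):
                rng = _pass_rng(seed, image_index, n)
                acc += _single_map(state, pixels, class_index, method,
                                   dropout_rate=p, rng=rng)
            values = normalize_map(acc / n_passes)
    return SaliencyMap(
        values=values,
        method=method,
        mode=mode,
        target_layer=f"block{len(state.blocks)}.conv",
        explained_class=explained_class,
    )


def mean_saliency_intensity(map_: SaliencyMap | np.ndarray) -> float:
    """MSI: the arithmetic mean of the normalized heatmap."""
    values = map_.values if isinstance(map_, SaliencyMap) else np.asarray(map_)
    if values.size == 0:
        raise DataError("saliency map is empty")
    return float(values.mean())


def saliency_pcc(map_a: SaliencyMap | np.ndarray, map_b: SaliencyMap | np.ndarray) -> float:
    """Pearson correlation between two maps; NaN (missing) when either map
    is constant."""
    a = (map_a.values if isinstance(map_a, SaliencyMap) else np.asarray(map_a)).ravel()
    b = (map_b.values if isinstance(map_b, SaliencyMap) else np.asarray(map_b)).ravel()
    if a.shape != b.shape:
        raise DataError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compute_msi_threshold(
    records: Iterable[tuple[float, str]], source: str = ""
) -> MSIThreshold:
    """D = min(max MSI over TP, max MSI over TN) from validation outcomes."""
    tp = [msi for msi, outcome in records if outcome == "TP"]
    tn = [msi for msi, outcome in records if outcome == "TN"]
    if not tp or not tn:
        raise CalibrationError(
            f"need at least one TP and one TN record (got {len(tp)} TP, {len(tn)} TN)"
        )
    max_tp, max_tn = max(tp), max(tn)
    return MSIThreshold(D=min(max_tp, max_tn), max_msi_tp=max_tp,
                        max_msi_tn=max_tn, source=source)


def xai_correction(
    predicted_label: str, msi: float, threshold: MSIThreshold
) -> tuple[str, bool]:
    """Flip the binary label iff MSI > D; keep it otherwise (equality keeps)."""
    if not 0.0 <= msi <= 1.0:
        raise ParameterError(f"msi must be in [0, 1], got {msi}")
    if predicted_label not in LABELS:
        raise ParameterError(f"unknown label {predicted_label!r}")
    if msi > threshold.D:
        other = LABELS[1 - LABELS.index(predicted_label)]
        return other, True
    return predicted_label, False
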