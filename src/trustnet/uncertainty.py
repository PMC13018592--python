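"""Monte-Carlo-dropout inference and entropy-based selective prediction.

The predictive distribution is the arithmetic mean of N stochastic forward
passes with dropout active at rate p; uncertainty is the Shannon entropy of
that mean, divided by log(C) so it spans [0, 1] for any class count
(0 = complete certainty, 1 = complete uncertainty).  A prediction is
*reliable* when H <= alpha (the mean validation entropy) and flagged for
expert review otherwise.  The dropout rate p* is the grid value that best
rank-separates the entropies of misclassified from correctly classified
validation samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import _nn
from .errors import DataError, ParameterError, StateError
from .network import TrustNet, _as_batch, _validate_pixels
from .phantoms import LABELS, LabeledImage

#: Dropout grid swept during calibration.
DEFAULT_P_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.5)
#: Stochastic forward passes per prediction; accuracy saturates around 10,
#: so 20 sits comfortably inside the plateau.
DEFAULT_N_PASSES = 20


@dataclass
class MCPrediction:
    per_pass_probs: np.ndarray  # (N, C)
    mean_probs: np.ndarray      # (C,)
    predicted_index: int
    entropy: float
    n_passes: int
    dropout_rate: float

    @property
    def predicted_label(self) -> str:
        return LABELS[self.predicted_index]


@dataclass
class UncertaintyThreshold:
    alpha: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass
class DropoutCalibration:
    grid: tuple[float, ...]
    summary: pd.DataFrame          # per-p quartiles of H for correct/incorrect
    separation: dict[float, float]  # per-p rank-discrimination score (NaN if undefined)
    p_star: float
    warning: str | None = None


def normalized_entropy(probs: Sequence[float] | np.ndarray) -> float:
    """H = -sum p log p / log C, with 0 log 0 := 0."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ParameterError("probability vector must be 1-D with >= 2 entries")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ParameterError("entries must be non-negative and sum to 1")
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz)) / np.log(p.size)
    return float(min(max(h, 0.0), 1.0))


def _pass_rng(seed: int, image_index: int, pass_index: int) -> np.random.Generator:
    # Per-image, per-pass substreams: pass n is the same stream regardless of
    # N, so sweeps over N are nested (larger N extends smaller N).
    return np.random.default_rng(np.random.SeedSequence((seed, image_index, pass_index)))


def mc_predict(
    state: TrustNet,
    image: LabeledImage | np.ndarray,
    n_passes: int = DEFAULT_N_PASSES,
    p: float = 0.01,
    seed: int = 0,
    image_index: int = 0,
) -> MCPrediction:
    """N stochastic forward passes with dropout rate p; batch norm stays in
    inference mode.  Deterministic given (seed, image_index)."""
    if not state.trained:
        raise StateError("mc_predict requires a trained network")
    if n_passes < 1:
        raise ParameterError("n_passes must be >= 1")
    if not 0.0 <= p < 1.0:
        raise ParameterError("dropout rate must be in [0, 1)")
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    _validate_pixels(pixels)
    x = pixels[None, None, :, :]
    passes = np.empty((n_passes, state.config.num_classes))
    for n in range(n_passes):
        rng = _pass_rng(seed, image_index, n)
        logits = state.forward(x, training=False, dropout_rate=p, rng=rng)
        passes[n] = _nn.softmax(logits)[0]
    mean = passes.mean(axis=0)
    return MCPrediction(
        per_pass_probs=passes,
        mean_probs=mean,
        predicted_index=int(mean.argmax()),
        entropy=normalized_entropy(mean),
        n_passes=n_passes,
        dropout_rate=p,
    )


def mc_predict_dataset(
    state: TrustNet,
    images: Sequence[LabeledImage],
    n_passes: int = DEFAULT_N_PASSES,
    p: float = 0.01,
    seed: int = 0,
) -> list[MCPrediction]:
    return [
        mc_predict(state, img, n_passes=n_passes, p=p, seed=seed, image_index=i)
        for i, img in enumerate(images)
    ]


def sweep_forward_passes(
    state: TrustNet,
    images: Sequence[LabeledImage],
    n_grid: Sequence[int] = (1, 2, 5, 10, 20),
    p: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of the mean MC prediction per ensemble size N.

    Pass streams are nested: the first N passes are identical across grid
    entries, so the sweep isolates the effect of N itself.
    """
    if len(images) == 0:
        raise DataError("validation set is empty")
    if any(n < 1 for n in n_grid):
        raise ParameterError("all grid values must be >= 1")
    n_max = max(n_grid)
    _, y = _as_batch(images)
    all_passes = np.empty((len(images), n_max, state.config.num_classes))
    for i, img in enumerate(images):
        pred = mc_predict(state, img, n_passes=n_max, p=p, seed=seed, image_index=i)
        all_passes[i] = pred.per_pass_probs
    rows = []
    for n in sorted(set(int(v) for v in n_grid)):
        mean = all_passes[:, :n, :].mean(axis=1)
        acc = float((mean.argmax(axis=1) == y).mean())
        rows.append({"n_passes": n, "accuracy": acc})
    return pd.DataFrame(rows)


def separation_score(h_correct: Sequence[float], h_incorrect: Sequence[float]) -> float:
    """Probability that a misclassified sample's entropy exceeds a correctly
    classified one's (ties count half) — the rank discrimination / AUC of H
    as a misclassification detector."""
    hc = np.asarray(h_correct, dtype=float)
    hm = np.asarray(h_incorrect, dtype=float)
    if hc.size == 0 or hm.size == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([hm, hc]))
    r_mis = ranks[: hm.size].sum()
    u = r_mis - hm.size * (hm.size + 1) / 2.0
    return float(u / (hm.size * hc.size))


def calibrate_dropout(
    state: TrustNet,
    images: Sequence[LabeledImage],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    n_passes: int = DEFAULT_N_PASSES,
    seed: int = 0,
) -> DropoutCalibration:
    """Pick the dropout rate whose entropies best separate misclassified
    from correctly classified validation samples (ties toward smaller p).

    Correctness is judged against the MC mean prediction at each p.  If no
    p yields any misclassification, the smallest grid value is selected and
    a warning is recorded.
    """
    if len(images) == 0:
        raise DataError("validation set is empty")
    _, y = _as_batch(images)
    grid = tuple(sorted(p_grid))
    rows = []
    separation: dict[float, float] = {}
    for p in grid:
        preds = mc_predict_dataset(state, images, n_passes=n_passes, p=p, seed=seed)
        h = np.array([pr.entropy for pr in preds])
        correct = np.array([pr.predicted_index for pr in preds]) == y
        score = separation_score(h[correct], h[~correct])
        separation[p] = score
        for group, sel in (("correct", correct), ("incorrect", ~correct)):
            vals = h[sel]
            rows.append(
                {
                    "p": p,
                    "group": group,
                    "count": int(sel.sum()),
                    "q1": float(np.quantile(vals, 0.25)) if vals.size else np.nan,
                    "median": float(np.median(vals)) if vals.size else np.nan,
                    "q3": float(np.quantile(vals, 0.75)) if vals.size else np.nan,
                }
            )
    defined = {p: s for p, s in separation.items() if not np.isnan(s)}
    warning = None
    if not defined:
        p_star = grid[0]
        warning = "no misclassified samples at any dropout rate; defaulting to smallest p"
    else:
        best = max(defined.values())
        # ascending grid + strict comparison -> ties break toward smaller p
        p_star = next(p for p in grid if defined.get(p, -np.inf) == best)
    return DropoutCalibration(
        grid=grid,
        summary=pd.DataFrame(rows),
        separation=separation,
        p_star=p_star,
        warning=warning,
    )


def compute_alpha(entropies: Sequence[float], source: str = "") -> UncertaintyThreshold:
    """alpha = arithmetic mean of the provided entropies."""
    h = np.asarray(entropies, dtype=float)
    if h.size == 0:
        raise DataError("cannot average an empty list of entropies")
    return UncertaintyThreshold(alpha=float(h.mean()), source=source)


def uq_filter(prediction: MCPrediction, threshold: UncertaintyThreshold) -> str:
    """'reliable' iff H <= alpha (inclusive); 'flagged' otherwise."""
    return "reliable" if prediction.entropy <= threshold.alpha else "flagged"
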