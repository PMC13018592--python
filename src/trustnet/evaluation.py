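"""Evaluation: classification metrics with Wilson intervals, MoRF
perturbation faithfulness, calibration (ECE/MCE/Brier + temperature
scaling), and risk-coverage analysis.

Conventions: stroke is the positive class; metrics are reported as
percentages; a metric with a zero denominator is *undefined* (NaN), never
silently zero; abstained (flagged) samples are excluded from the confusion
counts but tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from . import _nn
from .errors import CalibrationError, DataError, ParameterError
from .network import TrustNet
from .phantoms import LABELS
from .saliency import SaliencyMap


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int
    abstained: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricValue:
    percent: float       # NaN when undefined
    ci_low: float        # Wilson 95% bounds, percent scale; NaN for ratios
    ci_high: float       # that are not plain proportions (F1)


@dataclass
class MetricsReport:
    accuracy: MetricValue
    sensitivity: MetricValue
    specificity: MetricValue
    precision: MetricValue
    f1: MetricValue


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (as proportions)."""
    if trials < 1:
        raise ParameterError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ParameterError("successes must lie in [0, trials]")
    z = norm.ppf(0.5 + level / 2.0)
    phat = successes / trials
    denom = 1.0 + z**2 / trials
    centre = phat + z**2 / (2 * trials)
    half = z * np.sqrt(phat * (1 - phat) / trials + z**2 / (4 * trials**2))
    lo = 0.0 if successes == 0 else max(0.0, (centre - half) / denom)
    hi = 1.0 if successes == trials else min(1.0, (centre + half) / denom)
    return float(lo), float(hi)


def _metric(successes: int, trials: int) -> MetricValue:
    if trials == 0:
        return MetricValue(float("nan"), float("nan"), float("nan"))
    lo, hi = wilson_ci(successes, trials)
    return MetricValue(100.0 * successes / trials, 100.0 * lo, 100.0 * hi)


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    prec_trials = tp + fp
    sens_trials = tp + fn
    if prec_trials and sens_trials and (2 * tp + fp + fn) > 0:
        f1 = MetricValue(100.0 * 2 * tp / (2 * tp + fp + fn), float("nan"), float("nan"))
    else:
        f1 = MetricValue(float("nan"), float("nan"), float("nan"))
    return MetricsReport(
        accuracy=_metric(tp + tn, counts.total),
        sensitivity=_metric(tp, sens_trials),
        specificity=_metric(tn, tn + fp),
        precision=_metric(tp, prec_trials),
        f1=f1,
    )


def confusion_and_metrics(
    labels: Sequence[str], predictions: Sequence[str | None]
) -> tuple[ConfusionCounts, MetricsReport]:
    """Binary confusion counts and percent metrics with 95% Wilson CIs.

    ``None`` predictions are abstentions (flagged samples): excluded from
    the counts, tallied in ``counts.abstained``.
    """
    if len(labels) != len(predictions):
        raise DataError("labels and predictions must be aligned")
    if len(labels) == 0:
        raise DataError("empty evaluation set")
    pos = LABELS[0]  # stroke
    tp = fn = tn = fp = abst = 0
    for truth, pred in zip(labels, predictions):
        if pred is None:
            abst += 1
        elif truth == pos:
            tp += pred == pos
            fn += pred != pos
        else:
            tn += pred != pos
            fp += pred == pos
    counts = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp, abstained=abst)
    return counts, metrics_from_counts(counts)


# ---- MoRF perturbation --------------------------------------------------

@dataclass
class PerturbationCurve:
    fractions: np.ndarray
    mean_confidence: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    aupc: float
    aupc_stepsum: float
    n_images: int


def _pixel_order(values: np.ndarray) -> np.ndarray:
    # Descending saliency; ties resolved in row-major order via stable sort.
    return np.argsort(-values.ravel(), kind="stable")


def morf_curve(
    state: TrustNet,
    images: Sequence,
    maps: Sequence[SaliencyMap | np.ndarray],
    step: float = 0.05,
    replacement: float | None = None,
) -> PerturbationCurve:
    """Most-Relevant-First curve: remove the top-f fraction of pixels (by
    saliency) and track the deterministic softmax confidence of the
    originally predicted class; aggregate mean with a 95% normal band.

    ``replacement`` defaults to the mean intensity over the evaluated
    images (pass 0.0 for zero replacement).
    """
    if len(images) != len(maps):
        raise DataError("one saliency map per image required")
    if len(images) == 0:
        raise DataError("empty image set")
    pixel_stack = [img.pixels if hasattr(img, "pixels") else np.asarray(img)
                   for img in images]
    if replacement is None:
        replacement = float(np.mean([p.mean() for p in pixel_stack]))
    fractions = np.arange(0.0, 1.0 + step / 2.0, step)
    confs = np.empty((len(images), len(fractions)))
    for i, (pixels, smap) in enumerate(zip(pixel_stack, maps)):
        values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap)
        if values.shape != pixels.shape:
            raise DataError("saliency/image shape mismatch")
        order = _pixel_order(values)
        flat = pixels.ravel()
        n_pix = flat.size
        batch = np.empty((len(fractions), 1, *pixels.shape))
        for j, f in enumerate(fractions):
            k = int(round(f * n_pix))
            perturbed = flat.copy()
            perturbed[order[:k]] = replacement
            batch[j, 0] = perturbed.reshape(pixels.shape)
        probs = _nn.softmax(state.forward(batch, training=False))
        cls = int(probs[0].argmax())  # class predicted on the unperturbed image
        confs[i] = probs[:, cls]
    mean = confs.mean(axis=0)
    se = confs.std(axis=0, ddof=1) / np.sqrt(len(images)) if len(images) > 1 else np.zeros_like(mean)
    aupc = float(np.trapezoid(mean, fractions))
    return PerturbationCurve(
        fractions=fractions,
        mean_confidence=mean,
        ci_low=mean - 1.96 * se,
        ci_high=mean + 1.96 * se,
        aupc=aupc,
        aupc_stepsum=float(mean.sum()),  # comparability variant (grid sum)
        n_images=len(images),
    )


def aupc_and_select(
    curves: Mapping[str, PerturbationCurve]
) -> tuple[dict[str, float], str]:
    """Per-method unit-square AUPC and the most faithful method (lowest
    AUPC, ties toward gradcam)."""
    if not curves:
        raise DataError("no curves supplied")
    grids = [tuple(np.round(c.fractions, 12)) for c in curves.values()]
    if len(set(grids)) != 1:
        raise DataError("curves must share a common fraction grid")
    aupcs = {m: c.aupc for m, c in curves.items()}
    best = min(aupcs.values())
    ordered = sorted(aupcs, key=lambda m: (m != "gradcam", m))
    selected = next(m for m in ordered if aupcs[m] == best)
    return aupcs, selected


# ---- calibration --------------------------------------------------------

@dataclass
class CalibrationReport:
    ece: float
    mce: float
    brier: float
    temperature: float | None = None
    ece_scaled: float | None = None
    mce_scaled: float | None = None
    brier_scaled: float | None = None


def calibration_metrics(
    confidences: Sequence[float],
    correct: Sequence[bool],
    p_positive: Sequence[float],
    labels: Sequence[int],
    bins: int = 10,
) -> CalibrationReport:
    """ECE/MCE over equal-width confidence bins (empty bins skipped) and
    the binary Brier score on the positive-class probability."""
    conf = np.asarray(confidences, dtype=float)
    corr = np.asarray(correct, dtype=bool)
    ppos = np.asarray(p_positive, dtype=float)
    y = np.asarray(labels, dtype=int)
    if conf.size == 0:
        raise DataError("empty input")
    if bins < 1:
        raise ParameterError("bins must be >= 1")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(conf, edges[1:-1]), 0, bins - 1)
    ece, mce = 0.0, 0.0
    for b in range(bins):
        sel = idx == b
        if not sel.any():
            continue
        gap = abs(corr[sel].mean() - conf[sel].mean())
        ece += sel.mean() * gap
        mce = max(mce, gap)
    brier = float(np.mean((ppos - y) ** 2))
    return CalibrationReport(ece=float(ece), mce=float(mce), brier=brier)


def _nll(logits: np.ndarray, y: np.ndarray, temperature: float) -> float:
    return _nn.cross_entropy(_nn.softmax(logits / temperature), y)


def fit_temperature(
    logits: np.ndarray, labels: Sequence[int],
    bounds: tuple[float, float] = (0.05, 20.0), tol: float = 1e-5,
) -> float:
    """Temperature minimizing validation NLL of softmax(logits / T).

    Monotone scaling leaves argmax predictions unchanged.
    """
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=int)
    if logits.ndim != 2 or logits.shape[0] != y.shape[0]:
        raise DataError("logits must be (n, classes) aligned with labels")
    if len(np.unique(y)) < 2:
        raise CalibrationError("temperature fitting needs both classes present")
    res = minimize_scalar(lambda t: _nll(logits, y, t), bounds=bounds,
                          method="bounded", options={"xatol": tol})
    return float(res.x)


def calibration_with_temperature(
    val_logits: np.ndarray, val_labels: Sequence[int],
    test_logits: np.ndarray, test_labels: Sequence[int],
    bins: int = 10,
) -> CalibrationReport:
    """Full calibration report: raw metrics on the test logits, temperature
    fitted on validation, metrics recomputed after scaling."""
    test_logits = np.asarray(test_logits, dtype=float)
    y = np.asarray(test_labels, dtype=int)

    def _report(logits: np.ndarray) -> CalibrationReport:
        probs = _nn.softmax(logits)
        pred = probs.argmax(axis=1)
        return calibration_metrics(
            confidences=probs.max(axis=1), correct=pred == y,
            p_positive=probs[:, 0], labels=(y == 0).astype(int), bins=bins,
        )

    raw = _report(test_logits)
    t = fit_temperature(val_logits, val_labels)
    scaled = _report(test_logits / t)
    return CalibrationReport(
        ece=raw.ece, mce=raw.mce, brier=raw.brier, temperature=t,
        ece_scaled=scaled.ece, mce_scaled=scaled.mce, brier_scaled=scaled.brier,
    )


# ---- risk-coverage ------------------------------------------------------

def risk_coverage_curve(
    entropies: Sequence[float], correct: Sequence[bool]
) -> pd.DataFrame:
    """Selective-prediction trade-off: at threshold t, cover samples with
    H <= t; risk = 1 - accuracy among covered (NaN at zero coverage)."""
    h = np.asarray(entropies, dtype=float)
    c = np.asarray(correct, dtype=bool)
    if h.size == 0:
        raise DataError("empty input")
    thresholds = np.unique(np.concatenate([[0.0], np.unique(h), [1.0]]))
    rows = []
    for t in thresholds:
        covered = h <= t
        coverage = float(covered.mean())
        risk = float(1.0 - c[covered].mean()) if covered.any() else float("nan")
        rows.append({"threshold": float(t), "coverage": coverage, "risk": risk})
    return pd.DataFrame(rows)


def reliability_diagram_data(
    confidences: Sequence[float], correct: Sequence[bool], bins: int = 10
) -> pd.DataFrame:
    """Per-bin mean confidence, accuracy, and count (for plotting)."""
    conf = np.asarray(confidences, dtype=float)
    corr = np.asarray(correct, dtype=bool)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(conf, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "mean_confidence": float(conf[sel].mean()) if sel.any() else float("nan"),
            "accuracy": float(corr[sel].mean()) if sel.any() else float("nan"),
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)
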