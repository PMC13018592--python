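"""The cascaded decision pipeline: MC-dropout prediction -> entropy
rejection -> MSI-based label correction.

Stage order is fixed: the uncertainty stage filters first and the
explainability stage only ever sees retained samples.  Every input ends in
exactly one of three states — accepted, flagged for expert review (no
automated label), or flipped.  Setting alpha = 1 and D = 1 reduces the
cascade exactly to baseline MC-dropout classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, StateError
from .network import TrustNet
from .phantoms import LABELS, LabeledImage
from .saliency import (MSIThreshold, compute_msi_threshold, mean_saliency_intensity,
                       saliency_map, xai_correction)
from .uncertainty import (DEFAULT_N_PASSES, DEFAULT_P_GRID, UncertaintyThreshold,
                          calibrate_dropout, compute_alpha, mc_predict,
                          mc_predict_dataset, uq_filter)


@dataclass
class DecisionThresholds:
    p_star: float
    alpha: UncertaintyThreshold
    msi_threshold: MSIThreshold
    n_passes: int = DEFAULT_N_PASSES
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "p_star": self.p_star,
            "alpha": self.alpha.alpha,
            "alpha_source": self.alpha.source,
            "msi_D": self.msi_threshold.D,
            "max_msi_tp": self.msi_threshold.max_msi_tp,
            "max_msi_tn": self.msi_threshold.max_msi_tn,
            "n_passes": self.n_passes,
            "provenance": self.provenance,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionThresholds":
        data = json.loads(Path(path).read_text())
        return cls(
            p_star=data["p_star"],
            alpha=UncertaintyThreshold(alpha=data["alpha"], source=data.get("alpha_source", "")),
            msi_threshold=MSIThreshold(
                D=data["msi_D"], max_msi_tp=data["max_msi_tp"],
                max_msi_tn=data["max_msi_tn"],
            ),
            n_passes=data["n_passes"],
            provenance=data.get("provenance", {}),
        )


@dataclass
class CascadeResult:
    source_id: str
    baseline_label: str
    mean_probs: np.ndarray
    entropy: float
    status: str  # accepted | flagged_for_review | flipped
    final_label: str | None
    msi: float | None

    def __post_init__(self) -> None:
        if self.status == "flagged_for_review" and self.final_label is not None:
            raise StateError("flagged results carry no final label")
        if self.status == "flipped" and self.final_label == self.baseline_label:
            raise StateError("a flipped result must change the label")


def fit_cascade(
    state: TrustNet,
    val_images: Sequence[LabeledImage],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    n_passes: int = DEFAULT_N_PASSES,
    seed: int = 0,
    saliency_method: str = "gradcam",
    saliency_class: str = LABELS[0],
) -> DecisionThresholds:
    """Fit all thresholds on the validation split, sequentially.

    1. sweep the dropout grid -> p*;
    2. alpha = mean validation entropy at p*;
    3. MCD saliency + MSI per validation image, outcomes against ground
       truth -> D = min(max MSI_TP, max MSI_TN).

    The MSI maps all explain the same class — by default stroke, the
    hypodensity-evidence map — so that every MSI lives on one scale.  The
    min() in the threshold rule presumes commensurate group maxima; maps
    explaining different classes per sample have systematically different
    intensity statistics and would make the rule flip whole outcome groups.
    Since D is a sample maximum, it stabilizes only with a reasonably large
    validation split (dozens of TP and TN cases).
    """
    if not state.trained:
        raise StateError("fit_cascade requires a trained network")
    if len(val_images) == 0:
        raise DataError("validation split is empty")
    if len({img.label for img in val_images}) < 2:
        raise DataError("validation split must contain both labels")

    calib = calibrate_dropout(state, val_images, p_grid=p_grid,
                              n_passes=n_passes, seed=seed)
    p_star = calib.p_star

    preds = mc_predict_dataset(state, val_images, n_passes=n_passes, p=p_star, seed=seed)
    alpha = compute_alpha([pr.entropy for pr in preds],
                          source=f"validation mean entropy at p*={p_star}")

    records = []
    for i, (img, pred) in enumerate(zip(val_images, preds)):
        smap = saliency_map(
            state, img, explained_class=saliency_class,
            method=saliency_method, mode="mcd", p=p_star,
            n_passes=n_passes, seed=seed, image_index=i,
        )
        msi = mean_saliency_intensity(smap)
        truth = img.label
        predicted = pred.predicted_label
        if predicted == LABELS[0]:  # stroke = positive class
            outcome = "TP" if truth == LABELS[0] else "FP"
        else:
            outcome = "TN" if truth == LABELS[1] else "FN"
        records.append((msi, outcome))
    try:
        msi_threshold = compute_msi_threshold(
            records, source=f"validation MCD {saliency_method} at p*={p_star}"
        )
    except CalibrationError as err:
        raise CalibrationError(f"msi-threshold stage: {err}") from err

    return DecisionThresholds(
        p_star=p_star,
        alpha=alpha,
        msi_threshold=msi_threshold,
        n_passes=n_passes,
        provenance={
            "seed": seed,
            "n_validation": len(val_images),
            "p_grid": list(p_grid),
            "separation": {str(k): v for k, v in calib.separation.items()},
            "calibration_warning": calib.warning,
            "saliency_method": saliency_method,
            "saliency_class": saliency_class,
        },
    )


def run_cascade(
    state: TrustNet,
    thresholds: DecisionThresholds,
    images: Sequence[LabeledImage],
    seed: int = 0,
    saliency_method: str = "gradcam",
    saliency_class: str = LABELS[0],
) -> list[CascadeResult]:
    """Apply the fitted cascade to a batch of images."""
    if not isinstance(thresholds, DecisionThresholds):
        raise StateError("thresholds must be fitted DecisionThresholds")
    if not state.trained:
        raise StateError("run_cascade requires a trained network")
    results = []
    for i, img in enumerate(images):
        pred = mc_predict(state, img, n_passes=thresholds.n_passes,
                          p=thresholds.p_star, seed=seed, image_index=i)
        if uq_filter(pred, thresholds.alpha) == "flagged":
            results.append(CascadeResult(
                source_id=img.source_id, baseline_label=pred.predicted_label,
                mean_probs=pred.mean_probs, entropy=pred.entropy,
                status="flagged_for_review", final_label=None, msi=None,
            ))
            continue
        smap = saliency_map(
            state, img, explained_class=saliency_class,
            method=saliency_method, mode="mcd", p=thresholds.p_star,
            n_passes=thresholds.n_passes, seed=seed, image_index=i,
        )
        msi = mean_saliency_intensity(smap)
        final, flipped = xai_correction(pred.predicted_label, msi,
                                        thresholds.msi_threshold)
        results.append(CascadeResult(
            source_id=img.source_id, baseline_label=pred.predicted_label,
            mean_probs=pred.mean_probs, entropy=pred.entropy,
            status="flipped" if flipped else "accepted",
            final_label=final, msi=msi,
        ))
    return results


def results_to_frame(results: Sequence[CascadeResult]) -> pd.DataFrame:
    """Predictions table: one row per image, stroke probability included."""
    return pd.DataFrame(
        {
            "source_id": [r.source_id for r in results],
            "baseline_label": [r.baseline_label for r in results],
            "p_stroke_mean": [float(r.mean_probs[0]) for r in results],
            "entropy": [r.entropy for r in results],
            "status": [r.status for r in results],
            "final_label": [r.final_label if r.final_label is not None else "" for r in results],
            "msi": [r.msi if r.msi is not None else np.nan for r in results],
        }
    )
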