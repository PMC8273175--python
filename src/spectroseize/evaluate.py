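"""Channel- and record-level evaluation, analytic baselines, saliency maps.

Class accuracies are per-class recalls; the overall ("class-balanced")
accuracy is their unweighted mean, so it is insensitive to the roughly 2:1
non-seizure/seizure imbalance of ambulatory test sets. Records inherit
predictions from channels by the OR rule: a record is a seizure iff any of
its channels is predicted a seizure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve

POSITIVE = "sz"
NEGATIVE = "nsz"


@dataclass
class EvalReport:
    """Evaluation summary at one level (channel or record).

    Accuracies and F1 are percentages; ``overall_pct`` is the unweighted
    mean of the two class accuracies. ``confusion`` rows are truth, columns
    prediction, in (nsz, sz) order.
    """

    n: int
    acc_sz_pct: float
    acc_nsz_pct: float
    f1_pct: float
    confusion: pd.DataFrame
    precision: np.ndarray = field(repr=False, default=None)
    recall: np.ndarray = field(repr=False, default=None)
    pr_thresholds: np.ndarray = field(repr=False, default=None)
    undefined_classes: tuple[str, ...] = ()

    @property
    def overall_pct(self) -> float:
        return (self.acc_sz_pct + self.acc_nsz_pct) / 2.0


def _class_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                   proba_sz: Optional[np.ndarray]) -> EvalReport:
    classes = [NEGATIVE, POSITIVE]
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    undefined = tuple(c for c in classes if cm.loc[c].sum() == 0)
    accs = {}
    for c in classes:
        total = cm.loc[c].sum()
        accs[c] = 100.0 * cm.loc[c, c] / total if total else np.nan
    tp = cm.loc[POSITIVE, POSITIVE]
    fp = cm.loc[NEGATIVE, POSITIVE]
    fn = cm.loc[POSITIVE, NEGATIVE]
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
    report = EvalReport(n=len(y_true), acc_sz_pct=accs[POSITIVE],
                        acc_nsz_pct=accs[NEGATIVE], f1_pct=f1, confusion=cm,
                        undefined_classes=undefined)
    if proba_sz is not None and not undefined:
        prec, rec, thr = precision_recall_curve(
            (np.asarray(y_true) == POSITIVE).astype(int), proba_sz)
        report.precision, report.recall, report.pr_thresholds = prec, rec, thr
    return report


def channel_metrics(predictions: pd.DataFrame, truth: pd.DataFrame) -> EvalReport:
    """Evaluate per-channel predictions against truth labels.

    Both frames need key columns ``(patient_id, record_id, channel_index)``;
    ``predictions`` adds ``pred`` (sz/nsz) and optionally ``proba_sz``,
    ``truth`` adds ``cls`` (sz/nsz; 'excluded' rows must already be
    removed). The PR curve sweeps every distinct predicted probability.
    """
    keys = ["patient_id", "record_id", "channel_index"]
    merged = truth.merge(predictions, on=keys, how="inner", validate="one_to_one")
    if len(merged) != len(truth):
        raise ValueError("predictions do not cover every truth key")
    proba = merged["proba_sz"].to_numpy() if "proba_sz" in merged.columns else None
    return _class_metrics(merged["cls"].to_numpy(), merged["pred"].to_numpy(), proba)


def aggregate_record(channel_predictions: Sequence[str]) -> str:
    """OR rule: a record is a seizure iff any channel is predicted one."""
    preds = list(channel_predictions)
    if not preds:
        raise ValueError("need at least one channel prediction")
    bad = set(preds) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"unknown predictions {sorted(bad)}")
    return POSITIVE if POSITIVE in preds else NEGATIVE


def record_metrics(predictions: pd.DataFrame, truth: pd.DataFrame) -> EvalReport:
    """Record-level evaluation after OR aggregation of channel predictions.

    A record's seizure probability (for the PR curve) is the maximum of its
    channel seizure probabilities, consistent with the OR rule.
    """
    keys = ["patient_id", "record_id"]
    agg = {"pred": lambda c: aggregate_record(list(c))}
    if "proba_sz" in predictions.columns:
        agg["proba_sz"] = "max"
    pred_rec = predictions.groupby(keys).agg(pred=("pred", agg["pred"]),
                                             **({"proba_sz": ("proba_sz", "max")}
                                                if "proba_sz" in predictions.columns else {}))
    if "cls" not in truth.columns:
        raise ValueError("truth must carry a 'cls' column (sz/nsz)")
    truth_rec = truth.groupby(keys)["cls"].agg(
        lambda c: POSITIVE if (c == POSITIVE).any() else NEGATIVE)
    merged = pd.DataFrame({"cls": truth_rec}).join(pred_rec, how="inner")
    if len(merged) != len(truth_rec):
        raise ValueError("predictions do not cover every truth record")
    proba = merged["proba_sz"].to_numpy() if "proba_sz" in merged.columns else None
    return _class_metrics(merged["cls"].to_numpy(), merged["pred"].to_numpy(), proba)


def random_record_baseline(p_channel_sz: float, n_channels: int) -> float:
    """Probability that a random per-channel classifier labels a record a
    seizure under OR aggregation: ``1 - (1 - p)^n``.

    A coin-flip classifier on 4-channel records calls 93.75% of them
    seizures — the skew any record-level metric must be judged against.
    """
    if not 0.0 <= p_channel_sz <= 1.0:
        raise ValueError("p_channel_sz must lie in [0, 1]")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    return 1.0 - (1.0 - p_channel_sz) ** n_channels


def fp_rate_per_hour(nsz_accuracy_pct: float, segment_s: float = 90.0) -> float:
    """False positives per hour per channel when continuous data is cut into
    ``segment_s`` segments: ``(1 - acc/100) * 3600 / segment_s``."""
    if not 0.0 <= nsz_accuracy_pct <= 100.0:
        raise ValueError("nsz_accuracy_pct must lie in [0, 100]")
    if segment_s <= 0:
        raise ValueError("segment_s must be positive")
    return (1.0 - nsz_accuracy_pct / 100.0) * 3600.0 / segment_s


def saliency_map(model, image, target_class: int) -> np.ndarray:
    """Gradient saliency: |d class-score / d pixel|, max over color
    channels, min-max normalised to [0, 1].

    ``image`` may be a SpectrogramImage or a raw H x W x 3 array in [-1, 1];
    the returned map has the image's spatial shape.
    """
    px = np.asarray(image.pixels if hasattr(image, "pixels") else image, dtype=np.float32)
    if px.ndim != 3:
        raise ValueError("image must be H x W x C")
    if not hasattr(model, "input_gradient"):
        raise TypeError("model does not expose input gradients (not differentiable)")
    grad = model.input_gradient(px[None], int(target_class))[0]
    sal = np.abs(grad).max(axis=2)
    lo, hi = sal.min(), sal.max()
    if hi == lo:
        return np.zeros_like(sal)
    return (sal - lo) / (hi - lo)


def saliency_band_ratio(sal: np.ndarray, band_mask: np.ndarray) -> float:
    """Mean saliency inside a time-frequency band over mean outside it."""
    if sal.shape != band_mask.shape:
        raise ValueError("saliency map and mask shapes differ")
    inside = sal[band_mask].mean()
    outside = sal[~band_mask].mean()
    return float(inside / outside) if outside > 0 else np.inf
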