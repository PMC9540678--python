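"""Multiclass classification performance via one-vs-rest reductions.

Accuracy, sensitivity, specificity and positive predictive value are
tabulated per class from one-vs-rest confusion counts and then macro-
averaged with equal class weight.  Plain multiclass accuracy is also
reported: for K = 3 single-label predictions the two are linked exactly
by ``macro = (1 + 2 * plain) / 3``, since each misclassified row is
wrong in exactly two of the three one-vs-rest problems.  Zero-
denominator measures are reported missing rather than zero, except
sensitivity with a nonempty truth class, which is genuinely 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix

from .conformal import validate_probabilities

logger = logging.getLogger(__name__)

__all__ = [
    "confusion_counts",
    "per_class_measures",
    "macro_measures",
    "plain_accuracy",
    "calibration_table",
    "MEASURES",
]

MEASURES = ("accuracy", "sensitivity", "specificity", "ppv")


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> pd.DataFrame:
    """One-vs-rest TP/TN/FP/FN counts per class.

    Raises on empty inputs or labels outside ``{1..K}``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_pred.size == 0:
        raise ValueError("label vectors must be nonempty")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if v.min() < 1 or v.max() > n_classes:
            raise ValueError(f"{name} contains labels outside 1..{n_classes}")
    mcm = multilabel_confusion_matrix(y_true, y_pred, labels=np.arange(1, n_classes + 1))
    return pd.DataFrame(
        {
            "class": np.arange(1, n_classes + 1),
            "tp": mcm[:, 1, 1],
            "tn": mcm[:, 0, 0],
            "fp": mcm[:, 0, 1],
            "fn": mcm[:, 1, 0],
        }
    )


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den == 0, np.nan, out)


def per_class_measures(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-class accuracy, sensitivity, specificity and PPV.

    Undefined ratios (zero denominator) are NaN; sensitivity with
    ``TP = 0`` but a nonempty truth class is 0, matching the usual
    reading of "0% sensitivity" when a class is never predicted.
    """
    tp, tn = counts["tp"].to_numpy(float), counts["tn"].to_numpy(float)
    fp, fn = counts["fp"].to_numpy(float), counts["fn"].to_numpy(float)
    n = tp + tn + fp + fn
    return pd.DataFrame(
        {
            "class": counts["class"],
            "accuracy": _safe_ratio(tp + tn, n),
            "sensitivity": _safe_ratio(tp, tp + fn),
            "specificity": _safe_ratio(tn, tn + fp),
            "ppv": _safe_ratio(tp, tp + fp),
        }
    )


def macro_measures(per_class: pd.DataFrame) -> dict[str, float]:
    """Unweighted class means of the four measures, skipping missing values."""
    out = {}
    for m in MEASURES:
        vals = per_class[m].to_numpy(float)
        if np.isnan(vals).all():
            logger.warning("measure %s missing for every class; macro reported missing", m)
            out[m] = np.nan
            continue
        if np.isnan(vals).any():
            logger.warning("measure %s missing for some classes; macro skips them", m)
        out[m] = float(np.nanmean(vals))
    return out


def plain_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Ordinary multiclass accuracy (exact-match proportion)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("label vectors must be nonempty")
    return float(np.mean(y_true == y_pred))


def calibration_table(
    probs: np.ndarray, y_true: np.ndarray, n_bins: int
) -> pd.DataFrame:
    """Binned calibration by ordered predicted probability, per class.

    Observations are sorted by their predicted class-``y`` probability
    and cut into ``n_bins`` (near-)equal-count bins; each bin reports
    the mean predicted probability and the proportion truly in class
    ``y``.
    """
    probs = validate_probabilities(probs)
    y_true = np.asarray(y_true, dtype=int)
    n, k = probs.shape
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if n_bins > n:
        raise ValueError("more bins than observations")
    rows = []
    for y in range(1, k + 1):
        order = np.argsort(probs[:, y - 1], kind="stable")
        p_sorted = probs[order, y - 1]
        hit_sorted = (y_true[order] == y).astype(float)
        for b, (p_bin, h_bin) in enumerate(
            zip(np.array_split(p_sorted, n_bins), np.array_split(hit_sorted, n_bins))
        ):
            rows.append(
                {
                    "class": y,
                    "bin": b,
                    "n": p_bin.size,
                    "mean_predicted": float(p_bin.mean()),
                    "observed_proportion": float(h_bin.mean()),
                }
            )
    return pd.DataFrame(rows)
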