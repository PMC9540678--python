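"""Split-conformal set-valued (LABEL) classification.

The least-ambiguous-with-bounded-error-levels (LABEL) classifier turns
estimated conditional class probabilities into *sets* of plausible
labels.  On a calibration sample where the true class is observed, a
per-class threshold ``t_y`` is chosen as an order statistic of the
true-class predicted probabilities so that the set
``C_y = {x : P(y|x) >= t_y}`` covers class-``y`` observations with
probability at least ``1 - alpha_y`` under exchangeability.  Sets may
be empty (null sets) or contain several labels (ambiguous sets); both
are preserved here and only resolved downstream by the weighted
labeling bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "LabelSetMatrix",
    "validate_probabilities",
    "estimate_thresholds",
    "assign_label_sets",
    "empirical_coverage",
    "ambiguity_distribution",
]

_ROW_SUM_TOL = 1e-8


def validate_probabilities(probs: np.ndarray) -> np.ndarray:
    """Validate an ``(n, K)`` class-probability matrix.

    Rows must lie in ``[0, 1]`` and sum to 1 within ``1e-8``; rows
    within tolerance are renormalized exactly, anything worse raises.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] < 2:
        raise ValueError("probability matrix must be 2-D with at least 2 classes")
    if np.any(probs < -_ROW_SUM_TOL) or np.any(probs > 1 + _ROW_SUM_TOL):
        raise ValueError("probabilities must lie in [0, 1]")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
        raise ValueError("probability rows must sum to 1 within 1e-8")
    return np.clip(probs, 0.0, 1.0) / sums[:, None]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-class conformal thresholds with their target error levels.

    ``thresholds[y-1]`` is an order statistic of the calibration
    true-class probabilities for class ``y`` (never interpolated), and
    ``calibration_sizes[y-1]`` is the number of calibration
    observations of that class.
    """

    thresholds: np.ndarray
    alphas: np.ndarray
    calibration_sizes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", np.asarray(self.thresholds, dtype=float))
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        object.__setattr__(self, "calibration_sizes", np.asarray(self.calibration_sizes, dtype=int))
        if not (len(self.thresholds) == len(self.alphas) == len(self.calibration_sizes)):
            raise ValueError("thresholds, alphas and calibration_sizes must align")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class LabelSetMatrix:
    """Boolean membership of each observation in each class set."""

    member: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "member", np.asarray(self.member, dtype=bool))
        if self.member.ndim != 2:
            raise ValueError("member must be an (n, K) boolean matrix")

    @property
    def set_size(self) -> np.ndarray:
        return self.member.sum(axis=1)

    @property
    def n_classes(self) -> int:
        return self.member.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """One row per observation: per-class membership flags and set size."""
        k = self.n_classes
        df = pd.DataFrame(
            self.member.astype(int), columns=[f"in_set_class{y}" for y in range(1, k + 1)]
        )
        df.insert(0, "id", np.arange(len(df)))
        df["set_size"] = self.set_size
        return df


def _threshold_one_class(p: np.ndarray, alpha: float) -> float:
    """Smallest calibration probability whose tie-inclusive <=-count
    strictly exceeds ``(m + 1) * alpha - 1``.

    ``p`` holds the predicted probabilities of the *true* class for the
    calibration observations of one class.  Ties are counted in full,
    matching a brute-force scan of the defining condition.
    """
    m = p.size
    cut = (m + 1) * alpha - 1
    srt = np.sort(p)
    # tie-inclusive count of {p_j <= p_i} for each sorted candidate
    counts = np.searchsorted(srt, srt, side="right")
    ok = counts > cut
    # counts are nondecreasing along srt, so the first qualifying sorted
    # value is the minimum over all qualifying candidates
    return float(srt[np.argmax(ok)])


def estimate_thresholds(
    calib_probs: np.ndarray,
    calib_labels: np.ndarray,
    alphas: float | np.ndarray,
) -> ThresholdSet:
    """Estimate per-class conformal thresholds on the calibration half.

    For each class ``y``, the candidate scores are the predicted
    probabilities of the true class, ``p_i = P(Y_i | X_i)`` over
    calibration observations with ``Y_i = y``; the threshold is the
    smallest candidate whose tie-inclusive ``<=``-count exceeds
    ``(|I_y| + 1) * alpha_y - 1``.  With ``alpha_y = 0`` this is the
    minimum, so every calibration point of the class is covered.

    Raises
    ------
    ValueError
        If a class is absent from the calibration data or the
        probability matrix is ill-formed.
    """
    probs = validate_probabilities(calib_probs)
    labels = np.asarray(calib_labels, dtype=int)
    if labels.shape[0] != probs.shape[0]:
        raise ValueError("labels and probabilities must align")
    k = probs.shape[1]
    alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (k,)).copy()
    if np.any((alphas < 0) | (alphas >= 1)):
        raise ValueError("error levels alpha_y must lie in [0, 1)")
    true_p = probs[np.arange(len(labels)), labels - 1]
    thresholds = np.empty(k)
    sizes = np.empty(k, dtype=int)
    for y in range(1, k + 1):
        p_y = true_p[labels == y]
        if p_y.size == 0:
            raise ValueError(f"class {y} absent from calibration data; threshold not estimable")
        sizes[y - 1] = p_y.size
        thresholds[y - 1] = _threshold_one_class(p_y, alphas[y - 1])
    return ThresholdSet(thresholds, alphas, sizes)


def assign_label_sets(probs: np.ndarray, thresholds: ThresholdSet) -> LabelSetMatrix:
    """Form label sets ``C_y = {x : P(y|x) >= t_y}`` (inclusive ``>=``)."""
    probs = validate_probabilities(probs)
    if probs.shape[1] != thresholds.n_classes:
        raise ValueError(
            f"probability matrix has {probs.shape[1]} columns but "
            f"{thresholds.n_classes} thresholds were supplied"
        )
    return LabelSetMatrix(probs >= thresholds.thresholds[None, :])


def empirical_coverage(sets: LabelSetMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-class proportion of true-class rows whose set contains the truth.

    Classes with no observations get ``NaN`` (coverage undefined), with
    a logged warning; null sets never cover.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != sets.member.shape[0]:
        raise ValueError("labels must align with label sets")
    k = sets.n_classes
    cov = np.full(k, np.nan)
    for y in range(1, k + 1):
        mask = labels == y
        if not mask.any():
            logger.warning("class %d has no observations; coverage reported missing", y)
            continue
        cov[y - 1] = sets.member[mask, y - 1].mean()
    return cov


def ambiguity_distribution(
    sets: LabelSetMatrix, labels: np.ndarray | None = None
) -> pd.DataFrame:
    """Proportion of observations by label-set size, overall and by true class.

    Returns a tidy frame with columns ``group`` (``"overall"`` or
    ``"class{y}"``), ``set_size`` (0..K) and ``proportion``; proportions
    sum to 1 within each group.
    """
    k = sets.n_classes
    sizes = sets.set_size
    rows = []

    def _tab(group: str, s: np.ndarray) -> None:
        counts = np.bincount(s, minlength=k + 1)[: k + 1]
        for size, c in enumerate(counts):
            rows.append({"group": group, "set_size": size, "proportion": c / s.size})

    _tab("overall", sizes)
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        for y in range(1, k + 1):
            mask = labels == y
            if mask.any():
                _tab(f"class{y}", sizes[mask])
    return pd.DataFrame(rows)
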