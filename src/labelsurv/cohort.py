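"""Cohort container and stratified development-data splitting.

A cohort bundles the feature matrix, the (optionally missing) class
labels, and right-censored survival outcomes for one analysis sample.
Labels are integers ``1..K``; class ``K`` is the highest label value
present in the development data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Cohort", "SplitIndex", "split_development", "read_cohort_csv", "write_cohort_csv"]


@dataclass
class Cohort:
    """One analysis sample: features, class labels, survival outcomes.

    Parameters
    ----------
    features
        ``(n, p)`` numeric matrix.
    labels
        Length-``n`` integer labels in ``{1..K}``, or ``None`` for a
        deployment cohort where the true class is unobserved.
    time
        Length-``n`` nonnegative observed event/censoring times (days),
        or ``None`` if no survival outcome is available.
    event
        Length-``n`` boolean, ``True`` where the event (death) was
        observed rather than censored.
    n_classes
        Number of classes ``K``.  Defaults to ``max(labels)`` when
        labels are present.
    feature_names
        Optional column names, aligned with ``features``.
    """

    features: np.ndarray
    labels: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    n_classes: int | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] == 0 or self.features.shape[1] == 0:
            raise ValueError("features must be a nonempty 2-D matrix")
        n = self.features.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per row of features")
            if self.labels.min() < 1:
                raise ValueError("labels must be positive integers 1..K")
        if self.n_classes is None and self.labels is not None:
            self.n_classes = int(self.labels.max())
        if self.labels is not None and self.n_classes is not None:
            if self.labels.max() > self.n_classes:
                raise ValueError("label exceeds declared number of classes")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != (n,):
                raise ValueError("time must have one entry per observation")
            if np.any(self.time < 0):
                raise ValueError("survival times must be nonnegative")
            if self.event is None:
                raise ValueError("event indicator required wherever time is given")
            self.event = np.asarray(self.event, dtype=bool)
            if self.event.shape != (n,):
                raise ValueError("event must have one entry per observation")
        if not self.feature_names:
            self.feature_names = [f"x{j + 1}" for j in range(self.features.shape[1])]
        elif len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature columns")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row-subset (or resample, with repeated indices) of the cohort."""
        idx = np.asarray(idx)
        return Cohort(
            features=self.features[idx],
            labels=None if self.labels is None else self.labels[idx],
            time=None if self.time is None else self.time[idx],
            event=None if self.event is None else self.event[idx],
            n_classes=self.n_classes,
            feature_names=list(self.feature_names),
        )

    def select_features(self, names: list[str]) -> "Cohort":
        """Cohort restricted to the named feature columns (order preserved)."""
        missing = [c for c in names if c not in self.feature_names]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        cols = [self.feature_names.index(c) for c in names]
        return Cohort(
            features=self.features[:, cols],
            labels=self.labels,
            time=self.time,
            event=self.event,
            n_classes=self.n_classes,
            feature_names=list(names),
        )


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint index sets for the two halves of a development cohort."""

    part1: np.ndarray
    part2: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.part1, self.part2).size:
            raise ValueError("split halves must be disjoint")


def split_development(cohort: Cohort, seed: int) -> SplitIndex:
    """Stratified-by-label random split of a development cohort in half.

    Each class stratum is shuffled and divided as evenly as possible;
    odd strata place the extra observation in ``part1``.  Deterministic
    given ``seed``.

    Raises
    ------
    ValueError
        If labels are missing, or any class has fewer than two
        observations (no per-half representation possible).
    """
    if cohort.labels is None:
        raise ValueError("development cohort must have observed labels")
    rng = np.random.default_rng(seed)
    part1, part2 = [], []
    for y in range(1, cohort.n_classes + 1):
        idx = np.flatnonzero(cohort.labels == y)
        if idx.size < 2:
            raise ValueError(f"class {y} has fewer than 2 observations; cannot split")
        idx = rng.permutation(idx)
        half = (idx.size + 1) // 2  # odd stratum -> extra row in part1
        part1.append(idx[:half])
        part2.append(idx[half:])
    return SplitIndex(np.sort(np.concatenate(part1)), np.sort(np.concatenate(part2)))


def read_cohort_csv(
    path,
    feature_columns: list[str],
    label_column: str | None = None,
    time_column: str | None = None,
    event_column: str | None = None,
    n_classes: int | None = None,
) -> Cohort:
    """Read a cohort from a delimited text file with a header row."""
    df = pd.read_csv(path)
    missing = [c for c in feature_columns if c not in df.columns]
    if missing:
        raise KeyError(f"feature columns not in file: {missing}")
    labels = None
    if label_column is not None and label_column in df.columns:
        labels = df[label_column].to_numpy()
    time = event = None
    if time_column is not None and time_column in df.columns:
        if event_column is None or event_column not in df.columns:
            raise KeyError("event column required when a time column is given")
        time = df[time_column].to_numpy()
        event = df[event_column].to_numpy().astype(bool)
    return Cohort(
        features=df[feature_columns].to_numpy(dtype=float),
        labels=labels,
        time=time,
        event=event,
        n_classes=n_classes,
        feature_names=list(feature_columns),
    )


def write_cohort_csv(
    cohort: Cohort,
    path,
    label_column: str = "label",
    time_column: str = "time",
    event_column: str = "event",
) -> None:
    """Write a cohort to CSV (features plus whichever outcomes exist)."""
    df = pd.DataFrame(cohort.features, columns=cohort.feature_names)
    if cohort.labels is not None:
        df[label_column] = cohort.labels
    if cohort.time is not None:
        df[time_column] = cohort.time
        df[event_column] = cohort.event.astype(int)
    df.to_csv(path, index=False)
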