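"""Labeling-and-resampling strategies for downstream outcome estimation.

Three comparators:

* **standard practice** — argmax labels, one pass, Greenwood intervals
  for the survival estimates;
* **naive bootstrap** — argmax labels fixed per observation, the
  validation cohort resampled with replacement;
* **weighted labeling bootstrap** — the validation cohort resampled
  and, for every resampled observation, one label drawn uniformly from
  its conformal label set (uniformly over all K classes for null sets).

A label is redrawn independently for every appearance of a row in every
resample, so duplicated rows within one resample can receive different
labels — the reading that propagates the most label uncertainty.  Each
resample gets its own child RNG stream spawned from the root seed, so
runs are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .conformal import LabelSetMatrix, ThresholdSet, assign_label_sets, validate_probabilities
from .metrics import confusion_counts, macro_measures, per_class_measures, plain_accuracy
from .survival import DEFAULT_HORIZONS, stratified_summaries, survival_bias

__all__ = [
    "BootstrapRun",
    "naive_labels",
    "select_label",
    "select_labels",
    "run_weighted_bootstrap",
    "run_naive_bootstrap",
    "run_standard_practice",
    "summarize_bootstrap",
]


@dataclass
class BootstrapRun:
    """Per-resample draws and summaries from one bootstrap procedure."""

    method: str
    n_boot: int
    seed: int
    indices: np.ndarray  # (n_boot, n) resampled row indices
    labels: np.ndarray  # (n_boot, n) selected labels per resampled row
    metrics: pd.DataFrame  # one row per resample x measure
    survival: pd.DataFrame  # one row per resample x stratum x quantity
    metadata: dict = field(default_factory=dict)


def naive_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax labels; ties break toward the lowest class index."""
    probs = validate_probabilities(probs)
    return probs.argmax(axis=1) + 1


def select_label(set_row: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one label uniformly from a label set (all classes if null)."""
    set_row = np.asarray(set_row, dtype=bool)
    members = np.flatnonzero(set_row) + 1
    if members.size == 0:
        members = np.arange(1, set_row.size + 1)
    return int(rng.choice(members))


def select_labels(member: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized uniform label draw per row of a membership matrix."""
    member = np.asarray(member, dtype=float)
    null = member.sum(axis=1) == 0
    member[null] = 1.0  # null set: all classes equally likely
    cum = member.cumsum(axis=1)
    r = rng.random(member.shape[0]) * cum[:, -1]
    return (cum > r[:, None]).argmax(axis=1) + 1


def _classification_rows(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int, resample: int
) -> list[dict]:
    counts = confusion_counts(y_true, y_pred, n_classes)
    per_class = per_class_measures(counts)
    macro = macro_measures(per_class)
    rows = [
        {"resample": resample, "class": 0, "measure": f"macro_{m}", "value": v}
        for m, v in macro.items()
    ]
    rows.append(
        {
            "resample": resample,
            "class": 0,
            "measure": "plain_accuracy",
            "value": plain_accuracy(y_true, y_pred),
        }
    )
    for _, r in per_class.iterrows():
        for m in ("accuracy", "sensitivity", "specificity", "ppv"):
            rows.append(
                {"resample": resample, "class": int(r["class"]), "measure": m, "value": r[m]}
            )
    return rows


def _survival_rows(
    cohort: Cohort,
    pred_labels: np.ndarray,
    resample: int,
    horizons: tuple[float, ...],
    with_bias: bool,
) -> list[dict]:
    pred = stratified_summaries(cohort.time, cohort.event, pred_labels, cohort.n_classes, horizons)
    rows = []
    for y, s in pred.items():
        if s is None:
            continue
        rows.append(
            {"resample": resample, "stratum": y, "quantity": "median_days", "value": s.median_days}
        )
        for h, v in s.horizon_survival.items():
            rows.append(
                {"resample": resample, "stratum": y, "quantity": f"surv{int(h)}", "value": v}
            )
    if with_bias and cohort.labels is not None:
        obs = stratified_summaries(
            cohort.time, cohort.event, cohort.labels, cohort.n_classes, horizons
        )
        bias = survival_bias(pred, obs)
        for _, r in bias.iterrows():
            if r["quantity"] == "all":
                continue
            rows.append(
                {
                    "resample": resample,
                    "stratum": int(r["stratum"]),
                    "quantity": f"bias_{r['quantity']}",
                    "value": r["bias"],
                }
            )
    return rows


def _run_bootstrap(
    method: str,
    validation: Cohort,
    label_source,
    n_boot: int,
    seed: int,
    horizons: tuple[float, ...],
    compute_survival: bool,
) -> BootstrapRun:
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    n = validation.n
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_boot)
    indices = np.empty((n_boot, n), dtype=int)
    labels = np.empty((n_boot, n), dtype=int)
    metric_rows: list[dict] = []
    surv_rows: list[dict] = []
    has_outcome = compute_survival and validation.time is not None
    for b in range(n_boot):
        rng = np.random.default_rng(children[b])
        idx = rng.integers(0, n, size=n)
        indices[b] = idx
        labels[b] = label_source(idx, rng)
        if validation.labels is not None:
            metric_rows.extend(
                _classification_rows(validation.labels[idx], labels[b], validation.n_classes, b)
            )
        if has_outcome:
            surv_rows.extend(
                _survival_rows(
                    validation.subset(idx),
                    labels[b],
                    b,
                    horizons,
                    with_bias=validation.labels is not None,
                )
            )
    return BootstrapRun(
        method=method,
        n_boot=n_boot,
        seed=seed,
        indices=indices,
        labels=labels,
        metrics=pd.DataFrame(metric_rows),
        survival=pd.DataFrame(surv_rows),
        metadata={
            "label_redraw_policy": "independent per resampled row per resample",
            "horizons": list(horizons),
        },
    )


def run_weighted_bootstrap(
    validation: Cohort,
    probs: np.ndarray,
    thresholds: ThresholdSet,
    n_boot: int,
    seed: int,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    compute_survival: bool = True,
) -> BootstrapRun:
    """Weighted labeling bootstrap: resample, then draw one label per
    resampled observation from its conformal label set."""
    probs = validate_probabilities(probs)
    if probs.shape[0] != validation.n:
        raise ValueError("probability rows must align with the validation cohort")
    sets: LabelSetMatrix = assign_label_sets(probs, thresholds)
    member = sets.member

    def label_source(idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return select_labels(member[idx], rng)

    run = _run_bootstrap(
        "weighted_bootstrap", validation, label_source, n_boot, seed, horizons, compute_survival
    )
    run.metadata["thresholds"] = thresholds.thresholds.tolist()
    run.metadata["alphas"] = thresholds.alphas.tolist()
    return run


def run_naive_bootstrap(
    validation: Cohort,
    probs: np.ndarray,
    n_boot: int,
    seed: int,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    compute_survival: bool = True,
) -> BootstrapRun:
    """Naive bootstrap: argmax labels fixed per row, rows resampled."""
    fixed = naive_labels(probs)
    if fixed.shape[0] != validation.n:
        raise ValueError("probability rows must align with the validation cohort")

    def label_source(idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return fixed[idx]

    return _run_bootstrap(
        "naive_bootstrap", validation, label_source, n_boot, seed, horizons, compute_survival
    )


def run_standard_practice(
    validation: Cohort,
    probs: np.ndarray,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
) -> dict:
    """Single-pass argmax labeling: metrics plus Greenwood-interval survival.

    Returns a dict with ``labels``, ``metrics`` (tidy frame; empty when
    validation labels are absent), ``survival`` (per-stratum summaries
    with Greenwood CIs) and ``bias`` (vs observed-class strata, when
    labels and outcomes are both present).
    """
    pred = naive_labels(probs)
    if pred.shape[0] != validation.n:
        raise ValueError("probability rows must align with the validation cohort")
    metrics = pd.DataFrame(
        _classification_rows(validation.labels, pred, validation.n_classes, 0)
    ) if validation.labels is not None else pd.DataFrame()
    survival_rows = []
    bias = pd.DataFrame()
    summaries = {}
    if validation.time is not None:
        summaries = stratified_summaries(
            validation.time, validation.event, pred, validation.n_classes, horizons
        )
        for y, s in summaries.items():
            if s is None:
                continue
            survival_rows.append(
                {"stratum": y, "quantity": "median_days", "value": s.median_days,
                 "ci_low": np.nan, "ci_high": np.nan}
            )
            for h, v in s.horizon_survival.items():
                lo, hi = s.horizon_ci[h]
                survival_rows.append(
                    {"stratum": y, "quantity": f"surv{int(h)}", "value": v,
                     "ci_low": lo, "ci_high": hi}
                )
        if validation.labels is not None:
            obs = stratified_summaries(
                validation.time, validation.event, validation.labels,
                validation.n_classes, horizons,
            )
            bias = survival_bias(summaries, obs)
    return {
        "labels": pred,
        "metrics": metrics,
        "survival": pd.DataFrame(survival_rows),
        "bias": bias,
        "summaries": summaries,
    }


def summarize_bootstrap(run: BootstrapRun, level: float = 0.95) -> pd.DataFrame:
    """Mean and percentile interval of every stored per-resample statistic."""
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    frames = []
    for df, keys in ((run.metrics, ["class", "measure"]), (run.survival, ["stratum", "quantity"])):
        if df.empty:
            continue
        g = df.groupby(keys)["value"]
        summary = g.agg(
            mean="mean",
            ci_low=lambda v: np.nanpercentile(v, lo_q) if v.notna().any() else np.nan,
            ci_high=lambda v: np.nanpercentile(v, hi_q) if v.notna().any() else np.nan,
            n_resamples="size",
        ).reset_index()
        frames.append(summary)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.insert(0, "method", run.method)
    return out
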