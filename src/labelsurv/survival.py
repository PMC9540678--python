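"""Stratified Kaplan-Meier estimation and bias against observed-class strata.

The product-limit fit itself is delegated to :mod:`lifelines`; this
module extracts the per-event-time risk table, accumulates the plain
Greenwood variance, and adds the summaries used to compare predicted-
class stratification with observed-class stratification: median
survival time, survival probabilities at fixed horizons (90 and 365
days by default), Greenwood confidence intervals, and per-stratum bias
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "SurvivalSummary",
    "km_fit",
    "km_summary",
    "greenwood_ci",
    "stratified_summaries",
    "survival_bias",
    "DEFAULT_HORIZONS",
]

DEFAULT_HORIZONS = (90.0, 365.0)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the distinct event times of one stratum.

    ``survival[i]`` is the step value just after ``event_times[i]``;
    ties between deaths and censorings resolve deaths first, the
    standard product-limit convention.  ``greenwood_var`` is the plain-
    scale Greenwood variance of the survival estimate at each time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_var: np.ndarray
    n_total: int
    max_followup: float

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """Step-function lookup of S(t); S(t) = 1 before the first event."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(t), side="right") - 1
        if self.event_times.size == 0:  # no events observed: S(t) = 1 everywhere
            out = np.ones(idx.shape)
        else:
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if np.ndim(t) else float(out[0])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])


@dataclass
class SurvivalSummary:
    """Median and fixed-horizon survival for one stratum."""

    stratum: int | None
    n: int
    median_days: float  # NaN when the curve never reaches 0.5
    horizon_survival: dict = field(default_factory=dict)  # horizon -> S(h)
    horizon_ci: dict = field(default_factory=dict)  # horizon -> (lo, hi), Greenwood


def km_fit(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit fit with Greenwood variance.

    Raises
    ------
    ValueError
        On negative times or an empty sample.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("at least one observation required")
    if np.any(time < 0):
        raise ValueError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table  # indexed by time; deaths precede censorings at ties
    mask = table["observed"].to_numpy() > 0
    times = table.index.to_numpy(dtype=float)[mask]
    d = table["observed"].to_numpy(dtype=float)[mask]
    n_at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    surv = np.cumprod(1.0 - d / n_at_risk)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (n_at_risk * (n_at_risk - d))
    terms = np.where(n_at_risk == d, 0.0, terms)  # S(t)=0 there; variance 0
    var = surv**2 * np.cumsum(terms)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=n_at_risk.astype(int),
        events=d.astype(int),
        greenwood_var=var,
        n_total=time.size,
        max_followup=float(time.max()),
    )


def km_summary(
    curve: KMCurve,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    ci_level: float = 0.95,
    stratum: int | None = None,
) -> SurvivalSummary:
    """Median survival time and fixed-horizon survival probabilities.

    The median is the smallest event time with ``S(t) <= 0.5``, missing
    (NaN) when the curve never reaches 0.5 within follow-up.  Horizons
    beyond the last observed time return the last step value with a
    logged warning.
    """
    below = curve.survival <= 0.5
    median = float(curve.event_times[np.argmax(below)]) if below.any() else float("nan")
    horizon_survival, horizon_ci = {}, {}
    for h in horizons:
        if h > curve.max_followup and curve.survival_at(h) > 0:
            # extrapolating past follow-up with subjects still at risk
            logger.warning(
                "horizon %.0f beyond last observed time %.0f; using last step value",
                h,
                curve.max_followup,
            )
        horizon_survival[float(h)] = curve.survival_at(h)
        horizon_ci[float(h)] = greenwood_ci(curve, h, level=ci_level)
    return SurvivalSummary(
        stratum=stratum,
        n=curve.n_total,
        median_days=median,
        horizon_survival=horizon_survival,
        horizon_ci=horizon_ci,
    )


def greenwood_ci(curve: KMCurve, horizon: float, level: float = 0.95) -> tuple[float, float]:
    """Plain-scale Greenwood interval ``S(h) ± z·sqrt(var)``, clipped to [0, 1]."""
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    s = curve.survival_at(horizon)
    se = np.sqrt(curve.variance_at(horizon))
    z = stats.norm.ppf(0.5 + level / 2)
    return (max(0.0, s - z * se), min(1.0, s + z * se))


def stratified_summaries(
    time: np.ndarray,
    event: np.ndarray,
    strata_labels: np.ndarray,
    n_classes: int,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
) -> dict[int, SurvivalSummary | None]:
    """One KM fit and summary per class stratum; empty strata give ``None``."""
    strata_labels = np.asarray(strata_labels, dtype=int)
    out: dict[int, SurvivalSummary | None] = {}
    for y in range(1, n_classes + 1):
        mask = strata_labels == y
        if not mask.any():
            logger.warning("stratum %d empty; summary reported missing", y)
            out[y] = None
            continue
        curve = km_fit(np.asarray(time)[mask], np.asarray(event)[mask])
        out[y] = km_summary(curve, horizons=horizons, stratum=y)
    return out


def survival_bias(
    pred_summaries: dict[int, SurvivalSummary | None],
    obs_summaries: dict[int, SurvivalSummary | None],
) -> pd.DataFrame:
    """Bias of predicted-class-stratified estimates vs observed-class ones.

    Median bias is in days; horizon-survival bias is in percentage
    points (difference of survival probabilities times 100), with a
    relative-percent column alongside.  Missing medians propagate a
    missing bias with a reason code.
    """
    rows = []
    for y in sorted(obs_summaries):
        pred, obs = pred_summaries.get(y), obs_summaries[y]
        if pred is None or obs is None:
            rows.append(
                {
                    "stratum": y,
                    "quantity": "all",
                    "bias": np.nan,
                    "reason": "empty_stratum",
                }
            )
            continue
        med_bias = pred.median_days - obs.median_days
        rows.append(
            {
                "stratum": y,
                "quantity": "median_days",
                "bias": med_bias,
                "reason": "" if np.isfinite(med_bias) else "median_not_reached",
            }
        )
        for h in obs.horizon_survival:
            diff = pred.horizon_survival[h] - obs.horizon_survival[h]
            rel = (
                100.0 * diff / obs.horizon_survival[h]
                if obs.horizon_survival[h] > 0
                else np.nan
            )
            rows.append(
                {
                    "stratum": y,
                    "quantity": f"surv{int(h)}_pp",
                    "bias": 100.0 * diff,
                    "relative_pct": rel,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)
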