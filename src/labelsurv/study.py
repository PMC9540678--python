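"""End-to-end simulation study runner and cohort-level application.

One replicate of the study: simulate a cohort, fit the probability
estimator (on the whole development cohort for the naive methods, on
the first development half for the weighted method), estimate the
conformal thresholds on the second half, apply everything to the
validation cohort, and compute classification and survival outputs for
each requested method.  Replicates are aggregated with Monte Carlo
means and SDs; every summary is recomputable from the stored
per-replicate records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import bootstrap as bt
from . import conformal, estimators, simdata
from .cohort import Cohort, split_development

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "run_replicate", "run_study", "summarize_study", "apply_to_cohort"]

METHODS = ("standard_practice", "naive_bootstrap", "weighted_bootstrap")


@dataclass
class StudyResult:
    """Per-replicate records and run metadata for one simulation study."""

    coverage: pd.DataFrame  # replicate x scenario x method x class
    thresholds: pd.DataFrame  # replicate x scenario x class
    ambiguity: pd.DataFrame  # replicate x scenario x group x set_size
    metrics: pd.DataFrame  # replicate x scenario x method x class x measure
    survival: pd.DataFrame  # replicate x scenario x method x stratum x quantity
    failures: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _conformal_pipeline(rep: simdata.SimReplicate, alpha, estimator_spec, seed: int):
    """Split-fit-calibrate on the development cohort, sets on validation."""
    dev = rep.development.select_features(rep.feature_set)
    val = rep.validation.select_features(rep.feature_set)
    split = split_development(dev, seed)
    model = estimators.fit(estimator_spec, dev.subset(split.part1))
    calib_probs = estimators.predict_proba(model, dev.subset(split.part2).features)
    thresholds = conformal.estimate_thresholds(
        calib_probs, dev.labels[split.part2], alpha
    )
    val_probs = estimators.predict_proba(model, val.features)
    sets = conformal.assign_label_sets(val_probs, thresholds)
    return thresholds, val_probs, sets


def _naive_pipeline(rep: simdata.SimReplicate, estimator_spec):
    """Full-development fit for the argmax comparators."""
    dev = rep.development.select_features(rep.feature_set)
    val = rep.validation.select_features(rep.feature_set)
    model = estimators.fit(estimator_spec, dev)
    return estimators.predict_proba(model, val.features)


def run_replicate(
    scenario: int,
    config: simdata.SimConfig,
    seed: int,
    alpha: float | np.ndarray = 0.10,
    estimator_spec: str | dict = "multinomial_logit",
    n_boot: int = 500,
    methods: tuple[str, ...] = METHODS,
    compute_survival: bool = True,
) -> dict:
    """Run one simulation replicate; returns tidy per-replicate records."""
    rep = simdata.make_replicate(scenario, config, seed)
    val = rep.validation
    k = config.n_classes
    out: dict[str, list] = {"coverage": [], "thresholds": [], "ambiguity": [],
                            "metrics": [], "survival": []}

    thresholds, val_probs_w, sets = _conformal_pipeline(rep, alpha, estimator_spec, seed)
    cov_w = conformal.empirical_coverage(sets, val.labels)
    for y in range(k):
        out["coverage"].append(
            {"scenario": scenario, "method": "weighted", "class": y + 1, "coverage": cov_w[y]}
        )
        out["thresholds"].append(
            {"scenario": scenario, "class": y + 1, "threshold": thresholds.thresholds[y]}
        )
    amb = conformal.ambiguity_distribution(sets, val.labels)
    amb.insert(0, "scenario", scenario)
    out["ambiguity"] = amb.to_dict("records")

    naive_probs = _naive_pipeline(rep, estimator_spec)
    naive_lab = bt.naive_labels(naive_probs)
    for y in range(1, k + 1):
        mask = val.labels == y
        out["coverage"].append(
            {
                "scenario": scenario,
                "method": "naive",
                "class": y,
                "coverage": float(np.mean(naive_lab[mask] == y)) if mask.any() else np.nan,
            }
        )

    child = np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2**31)
    if "standard_practice" in methods:
        sp = bt.run_standard_practice(val, naive_probs)
        _collect(out, scenario, "standard_practice", sp["metrics"], sp["survival"], sp["bias"])
    if "naive_bootstrap" in methods:
        run = bt.run_naive_bootstrap(
            val, naive_probs, n_boot, int(child), compute_survival=compute_survival
        )
        _collect_boot(out, scenario, run)
    if "weighted_bootstrap" in methods:
        run = bt.run_weighted_bootstrap(
            val, val_probs_w, thresholds, n_boot, int(child) + 1,
            compute_survival=compute_survival,
        )
        _collect_boot(out, scenario, run)
    return out


def _collect(out, scenario, method, metrics, survival, bias):
    for _, r in metrics.iterrows():
        out["metrics"].append(
            {"scenario": scenario, "method": method, "class": int(r["class"]),
             "measure": r["measure"], "value": r["value"]}
        )
    for _, r in survival.iterrows():
        out["survival"].append(
            {"scenario": scenario, "method": method, "stratum": int(r["stratum"]),
             "quantity": r["quantity"], "value": r["value"],
             "ci_low": r.get("ci_low", np.nan), "ci_high": r.get("ci_high", np.nan)}
        )
    if bias is not None and not bias.empty:
        for _, r in bias.iterrows():
            if r["quantity"] == "all":
                continue
            out["survival"].append(
                {"scenario": scenario, "method": method, "stratum": int(r["stratum"]),
                 "quantity": f"bias_{r['quantity']}", "value": r["bias"],
                 "ci_low": np.nan, "ci_high": np.nan}
            )


def _collect_boot(out, scenario, run: bt.BootstrapRun):
    summary = bt.summarize_bootstrap(run)
    for _, r in summary.iterrows():
        if "measure" in r and isinstance(r.get("measure"), str):
            out["metrics"].append(
                {"scenario": scenario, "method": run.method, "class": int(r["class"]),
                 "measure": r["measure"], "value": r["mean"],
                 "ci_low": r["ci_low"], "ci_high": r["ci_high"]}
            )
        if isinstance(r.get("quantity"), str):
            out["survival"].append(
                {"scenario": scenario, "method": run.method, "stratum": int(r["stratum"]),
                 "quantity": r["quantity"], "value": r["mean"],
                 "ci_low": r["ci_low"], "ci_high": r["ci_high"]}
            )


def run_study(
    config: simdata.SimConfig,
    scenarios: tuple[int, ...] = (1, 2, 3),
    n_reps: int = 1000,
    n_boot: int = 500,
    alpha: float = 0.10,
    estimator_spec: str | dict = "multinomial_logit",
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    n_jobs: int = 1,
    compute_survival: bool = True,
) -> StudyResult:
    """Run the full simulation study: ``n_reps`` replicates per scenario.

    Per-replicate child seeds are spawned from the root seed, so the
    result is identical regardless of worker count.  Replicate failures
    are recorded and the study aborts only if more than 1% fail.
    """
    rep_seeds = [
        int(s) % (2**31)
        for s in np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint64)
    ]
    tasks = [(sc, r, rep_seeds[r]) for sc in scenarios for r in range(n_reps)]

    def _one(sc, r, s):
        try:
            rec = run_replicate(
                sc, config, s, alpha=alpha, estimator_spec=estimator_spec,
                n_boot=n_boot, methods=methods, compute_survival=compute_survival,
            )
            return (sc, r, s, rec, None)
        except Exception as exc:  # noqa: BLE001 - failure policy: log and continue
            return (sc, r, s, None, repr(exc))

    results = Parallel(n_jobs=n_jobs)(delayed(_one)(*t) for t in tasks)
    frames: dict[str, list] = {k: [] for k in ("coverage", "thresholds", "ambiguity",
                                               "metrics", "survival")}
    failures = []
    for sc, r, s, rec, err in results:
        if err is not None:
            logger.error("replicate %d scenario %d (seed %d) failed: %s", r, sc, s, err)
            failures.append({"scenario": sc, "replicate": r, "seed": s, "error": err})
            continue
        for key, rows in rec.items():
            for row in rows:
                row = dict(row)
                row["replicate"] = r
                frames[key].append(row)
    if len(failures) > 0.01 * len(tasks):
        raise RuntimeError(f"{len(failures)} of {len(tasks)} replicates failed; aborting")
    return StudyResult(
        coverage=pd.DataFrame(frames["coverage"]),
        thresholds=pd.DataFrame(frames["thresholds"]),
        ambiguity=pd.DataFrame(frames["ambiguity"]),
        metrics=pd.DataFrame(frames["metrics"]),
        survival=pd.DataFrame(frames["survival"]),
        failures=pd.DataFrame(failures),
        metadata={
            "n_reps": n_reps, "n_boot": n_boot, "alpha": alpha, "seed": seed,
            "scenarios": list(scenarios), "estimator": estimator_spec,
            "methods": list(methods),
        },
    )


def summarize_study(result: StudyResult) -> dict[str, pd.DataFrame]:
    """Publication-style tables from the stored per-replicate records.

    The "Monte Carlo SE" column is the SD of the statistic across
    replicates (the across-replicate spread); the SE of the Monte Carlo
    mean is also stored as ``se_mean``.
    """

    def _agg(df, keys, value):
        g = df.groupby(keys)[value]
        t = g.agg(mean="mean", mc_se="std", n="size").reset_index()
        t["se_mean"] = t["mc_se"] / np.sqrt(t["n"])
        return t

    tables = {
        "coverage": _agg(result.coverage, ["scenario", "method", "class"], "coverage"),
        "thresholds": _agg(result.thresholds, ["scenario", "class"], "threshold"),
        "ambiguity": _agg(result.ambiguity, ["scenario", "group", "set_size"], "proportion"),
        "metrics": _agg(result.metrics, ["scenario", "method", "class", "measure"], "value"),
    }
    if not result.survival.empty:
        surv = result.survival.copy()
        g = surv.groupby(["scenario", "method", "stratum", "quantity"])["value"]
        tables["survival"] = g.agg(
            mean="mean",
            mc_se="std",
            ci_low=lambda v: np.nanpercentile(v, 2.5) if v.notna().any() else np.nan,
            ci_high=lambda v: np.nanpercentile(v, 97.5) if v.notna().any() else np.nan,
            n="size",
        ).reset_index()
    return tables


def pilot_anchor_statistics(
    config: simdata.SimConfig,
    n_reps: int,
    alpha: float = 0.10,
    seed: int = 0,
    estimator_spec: str | dict = "multinomial_logit",
) -> dict:
    """Cheap anchor statistics for generator calibration.

    Computes, over ``n_reps`` pilot replicates: the marginal class
    balance, scenario-2 naive macro accuracy, and the scenario-1 and
    scenario-2 single-label-set shares at the given error level.  No
    bootstrap is involved.
    """
    from .metrics import confusion_counts, macro_measures, per_class_measures

    rep_seeds = [
        int(s) % (2**31)
        for s in np.random.SeedSequence([seed, 7]).generate_state(n_reps, dtype=np.uint64)
    ]
    balance = np.zeros(config.n_classes)
    acc2, single1, single2, single1_class1 = [], [], [], []
    for s in rep_seeds:
        rep1 = simdata.make_replicate(1, config, s)
        labels_all = np.concatenate([rep1.development.labels, rep1.validation.labels])
        balance += np.bincount(labels_all, minlength=config.n_classes + 1)[1:] / labels_all.size

        _, _, sets1 = _conformal_pipeline(rep1, alpha, estimator_spec, s)
        sizes = sets1.set_size
        single1.append(float(np.mean(sizes == 1)))
        mask1 = rep1.validation.labels == 1
        single1_class1.append(float(np.mean(sizes[mask1] == 1)))

        rep2 = simdata.make_replicate(2, config, s)
        probs2 = _naive_pipeline(rep2, estimator_spec)
        pred2 = bt.naive_labels(probs2)
        counts = confusion_counts(rep2.validation.labels, pred2, config.n_classes)
        acc2.append(macro_measures(per_class_measures(counts))["accuracy"])
        _, _, sets2 = _conformal_pipeline(rep2, alpha, estimator_spec, s)
        single2.append(float(np.mean(sets2.set_size == 1)))
    return {
        "class_balance": tuple(np.round(balance / n_reps, 4)),
        "scenario2_naive_macro_accuracy": float(np.mean(acc2)),
        "scenario1_single_share": float(np.mean(single1)),
        "scenario1_single_share_class1": float(np.mean(single1_class1)),
        "scenario2_single_share": float(np.mean(single2)),
        "n_reps": n_reps,
    }


def apply_to_cohort(
    development: Cohort,
    validation: Cohort,
    alpha: float | np.ndarray = 0.10,
    estimator_spec: str | dict = "multinomial_logit",
    n_boot: int = 500,
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
) -> dict:
    """Apply the three methods to user-supplied development/validation data.

    The development cohort must be labeled.  When validation labels are
    absent, coverage and classification metrics are omitted; when the
    survival columns are absent, survival estimation is skipped with a
    warning and classification still runs.
    """
    if development.labels is None:
        raise ValueError("development cohort must have labels")
    if development.feature_names != validation.feature_names:
        raise ValueError(
            "feature columns differ between cohorts: "
            f"{development.feature_names} vs {validation.feature_names}"
        )
    if validation.time is None:
        logger.warning("validation cohort has no survival columns; survival skipped")
    rep = simdata.SimReplicate(
        development=development,
        validation=validation,
        true_probs_development=np.empty(0),
        true_probs_validation=np.empty(0),
        scenario=0,
        feature_set=list(development.feature_names),
        seed=seed,
    )
    thresholds, val_probs, sets = _conformal_pipeline(rep, alpha, estimator_spec, seed)
    naive_probs = _naive_pipeline(rep, estimator_spec)
    out = {
        "thresholds": thresholds,
        "label_sets": sets,
        "ambiguity": conformal.ambiguity_distribution(sets, validation.labels),
        "coverage": (
            conformal.empirical_coverage(sets, validation.labels)
            if validation.labels is not None
            else None
        ),
    }
    child = np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2**31)
    if "standard_practice" in methods:
        out["standard_practice"] = bt.run_standard_practice(validation, naive_probs)
    if "naive_bootstrap" in methods:
        out["naive_bootstrap"] = bt.summarize_bootstrap(
            bt.run_naive_bootstrap(validation, naive_probs, n_boot, int(child))
        )
    if "weighted_bootstrap" in methods:
        out["weighted_bootstrap"] = bt.summarize_bootstrap(
            bt.run_weighted_bootstrap(validation, val_probs, thresholds, n_boot, int(child) + 1)
        )
    return out
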