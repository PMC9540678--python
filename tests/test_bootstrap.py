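import numpy as np
import pytest

from labelsurv import (
    naive_labels,
    run_naive_bootstrap,
    run_standard_practice,
    run_weighted_bootstrap,
    select_label,
    select_labels,
    summarize_bootstrap,
)
from labelsurv.conformal import ThresholdSet


def _singleton_probs(labels, k=3, hi=0.9):
    probs = np.full((labels.size, k), (1 - hi) / (k - 1))
    probs[np.arange(labels.size), labels - 1] = hi
    return probs


def test_naive_labels_argmax_and_tie_break():
    probs = np.array([[0.2, 0.5, 0.3], [0.4, 0.4, 0.2], [0.1, 0.1, 0.8]])
    np.testing.assert_array_equal(naive_labels(probs), [2, 1, 3])  # tie -> lowest index


def test_select_label_singleton_deterministic():
    rng = np.random.default_rng(0)
    assert select_label(np.array([False, True, False]), rng) == 2


def test_select_label_uniform_over_pair_and_null():
    rng = np.random.default_rng(1)
    n = 10_000
    pair = np.array([select_label(np.array([True, False, True]), rng) for _ in range(n)])
    se = np.sqrt(0.25 / n)
    assert np.mean(pair == 1) == pytest.approx(0.5, abs=3 * se)
    assert np.all(np.isin(pair, [1, 3]))
    null = np.array([select_label(np.zeros(3, bool), rng) for _ in range(n)])
    se3 = np.sqrt((1 / 3) * (2 / 3) / n)
    for y in (1, 2, 3):
        assert np.mean(null == y) == pytest.approx(1 / 3, abs=3 * se3)


def test_select_labels_matches_rowwise_semantics():
    rng = np.random.default_rng(2)
    member = np.array(
        [[True, False, False], [True, True, True], [False, False, False]], dtype=bool
    )
    draws = np.array([select_labels(member, rng) for _ in range(9000)])
    assert np.all(draws[:, 0] == 1)  # singleton always returned
    se3 = np.sqrt((1 / 3) * (2 / 3) / 9000)
    for col in (1, 2):  # full set and null set both uniform over all 3
        for y in (1, 2, 3):
            assert np.mean(draws[:, col] == y) == pytest.approx(1 / 3, abs=3 * se3)


def test_select_labels_does_not_mutate_input():
    member = np.zeros((2, 3), bool)
    select_labels(member, np.random.default_rng(0))
    assert not member.any()


def test_weighted_equals_naive_when_sets_are_argmax_singletons(toy_cohort):
    labels = toy_cohort.labels
    probs = _singleton_probs(labels)
    thresholds = ThresholdSet(np.array([0.5, 0.5, 0.5]), np.full(3, 0.1), np.full(3, 20))
    w = run_weighted_bootstrap(toy_cohort, probs, thresholds, n_boot=5, seed=3)
    nv = run_naive_bootstrap(toy_cohort, probs, n_boot=5, seed=3)
    np.testing.assert_array_equal(w.indices, nv.indices)  # same resample streams
    np.testing.assert_array_equal(w.labels, nv.labels)  # singletons leave no choice
    for col in ("value",):
        np.testing.assert_allclose(
            w.metrics.sort_values(["resample", "class", "measure"])[col].to_numpy(),
            nv.metrics.sort_values(["resample", "class", "measure"])[col].to_numpy(),
        )


def test_bootstrap_reproducible_and_seed_sensitive(toy_cohort):
    probs = _singleton_probs(toy_cohort.labels)
    a = run_naive_bootstrap(toy_cohort, probs, n_boot=4, seed=7)
    b = run_naive_bootstrap(toy_cohort, probs, n_boot=4, seed=7)
    np.testing.assert_array_equal(a.indices, b.indices)
    assert a.metrics.equals(b.metrics)
    c = run_naive_bootstrap(toy_cohort, probs, n_boot=4, seed=8)
    assert not np.array_equal(a.indices, c.indices)


def test_naive_bootstrap_labels_fixed_per_row(toy_cohort):
    probs = np.random.default_rng(4).dirichlet(np.ones(3), size=toy_cohort.n)
    fixed = naive_labels(probs)
    run = run_naive_bootstrap(toy_cohort, probs, n_boot=6, seed=0)
    for b in range(6):
        np.testing.assert_array_equal(run.labels[b], fixed[run.indices[b]])


def test_identity_resample_matches_standard_practice(toy_cohort, monkeypatch):
    """With the resample forced to the identity, one naive bootstrap draw
    reproduces the standard-practice metrics exactly."""
    probs = np.random.default_rng(5).dirichlet(np.ones(3), size=toy_cohort.n)

    real_default_rng = np.random.default_rng

    class IdentityResampleRNG:
        def __init__(self, seed):
            self._rng = real_default_rng(seed)

        def integers(self, low, high=None, size=None):
            return np.arange(size)

        def __getattr__(self, name):
            return getattr(self._rng, name)

    import labelsurv.bootstrap as bt_module

    monkeypatch.setattr(bt_module.np.random, "default_rng", IdentityResampleRNG)
    run = run_naive_bootstrap(toy_cohort, probs, n_boot=1, seed=0)
    monkeypatch.undo()
    sp = run_standard_practice(toy_cohort, probs)
    key = ["class", "measure"]
    merged = run.metrics.merge(sp["metrics"], on=key, suffixes=("_boot", "_sp"))
    np.testing.assert_allclose(
        merged["value_boot"].to_numpy(), merged["value_sp"].to_numpy(), equal_nan=True
    )


def test_n_boot_validation(toy_cohort):
    probs = _singleton_probs(toy_cohort.labels)
    with pytest.raises(ValueError, match="n_boot"):
        run_naive_bootstrap(toy_cohort, probs, n_boot=0, seed=0)


def test_summarize_bootstrap_matches_recomputation(toy_cohort):
    probs = np.random.default_rng(6).dirichlet(np.ones(3), size=toy_cohort.n)
    run = run_naive_bootstrap(toy_cohort, probs, n_boot=20, seed=1)
    summary = summarize_bootstrap(run)
    row = summary[
        (summary["measure"] == "macro_accuracy") & (summary["class"] == 0)
    ].iloc[0]
    vals = run.metrics[run.metrics["measure"] == "macro_accuracy"]["value"].to_numpy()
    assert row["mean"] == pytest.approx(vals.mean())
    assert row["ci_low"] == pytest.approx(np.percentile(vals, 2.5))
    assert row["ci_high"] == pytest.approx(np.percentile(vals, 97.5))
    assert row["n_resamples"] == 20


def test_standard_practice_outputs(toy_cohort):
    probs = _singleton_probs(toy_cohort.labels)
    sp = run_standard_practice(toy_cohort, probs)
    np.testing.assert_array_equal(sp["labels"], toy_cohort.labels)
    macro = sp["metrics"]
    assert (
        macro[(macro["measure"] == "macro_accuracy")]["value"].iloc[0] == pytest.approx(1.0)
    )
    surv = sp["survival"]
    cis = surv[surv.quantity.str.startswith("surv")]
    assert ((cis.ci_low <= cis.value) & (cis.value <= cis.ci_high)).all()
    med_bias = sp["bias"][sp["bias"].quantity == "median_days"]["bias"]
    assert np.nansum(np.abs(med_bias)) == pytest.approx(0.0)  # perfect labels -> no bias


def test_compute_survival_flag_skips_survival(toy_cohort):
    probs = _singleton_probs(toy_cohort.labels)
    run = run_naive_bootstrap(toy_cohort, probs, n_boot=3, seed=0, compute_survival=False)
    assert run.survival.empty
    assert not run.metrics.empty
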