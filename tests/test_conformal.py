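import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labelsurv import (
    ambiguity_distribution,
    assign_label_sets,
    empirical_coverage,
    estimate_thresholds,
)
from labelsurv.conformal import ThresholdSet, _threshold_one_class, validate_probabilities


def brute_force_threshold(p, alpha):
    """Independent oracle: scan every candidate for the defining condition.

    The threshold is the smallest candidate probability whose
    tie-inclusive <=-count strictly exceeds (m+1)*alpha - 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    cut = (m + 1) * alpha - 1
    qualifying = [pi for pi in p if np.sum(p <= pi) > cut]
    return min(qualifying)


# ---------------------------------------------------------------- thresholds


def test_threshold_nine_point_example():
    # m=9, alpha=0.1: cut = 0, first candidate with count >= 1 is the minimum
    p = np.arange(0.1, 1.0, 0.1)
    assert _threshold_one_class(p, 0.1) == pytest.approx(0.1)


def test_threshold_three_point_half_alpha():
    # m=3, alpha=0.5: cut = 1, need tie-inclusive count > 1 -> 0.5
    p = np.array([0.2, 0.5, 0.8])
    assert _threshold_one_class(p, 0.5) == pytest.approx(0.5)


def test_threshold_alpha_zero_is_minimum():
    p = np.array([0.4, 0.05, 0.9, 0.3])
    assert _threshold_one_class(p, 0.0) == pytest.approx(0.05)


def test_threshold_ties_counted_in_full():
    # four copies of 0.3 and one 0.7; alpha=0.5, m=5 -> cut=2.
    # count(p <= 0.3) = 4 > 2, so the threshold is 0.3 despite rank.
    p = np.array([0.3, 0.3, 0.3, 0.3, 0.7])
    assert _threshold_one_class(p, 0.5) == pytest.approx(0.3)
    assert _threshold_one_class(p, 0.5) == pytest.approx(brute_force_threshold(p, 0.5))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    probs=st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50
    ),
    alpha=st.floats(min_value=0.0, max_value=0.99, allow_nan=False),
    round_to=st.sampled_from([None, 1, 2]),
)
def test_threshold_matches_brute_force_oracle(probs, alpha, round_to):
    p = np.asarray(probs)
    if round_to is not None:  # coarse rounding manufactures ties
        p = np.round(p, round_to)
    assert _threshold_one_class(p, alpha) == pytest.approx(brute_force_threshold(p, alpha))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_threshold_monotone_in_alpha(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(30)
    alphas = [0.0, 0.05, 0.1, 0.3, 0.6, 0.9]
    ts = [_threshold_one_class(p, a) for a in alphas]
    assert all(t1 <= t2 for t1, t2 in zip(ts, ts[1:]))


def test_estimate_thresholds_row_order_invariant():
    rng = np.random.default_rng(3)
    probs = rng.dirichlet(np.ones(3), size=120)
    labels = rng.integers(1, 4, size=120)
    t1 = estimate_thresholds(probs, labels, 0.1)
    perm = rng.permutation(120)
    t2 = estimate_thresholds(probs[perm], labels[perm], 0.1)
    np.testing.assert_allclose(t1.thresholds, t2.thresholds)


def test_estimate_thresholds_errors():
    probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
    with pytest.raises(ValueError, match="class 3 absent"):
        estimate_thresholds(probs, np.array([1, 2]), 0.1)
    with pytest.raises(ValueError, match="alpha"):
        estimate_thresholds(probs, np.array([1, 3]), 1.0)
    with pytest.raises(ValueError, match="sum to 1"):
        estimate_thresholds(np.array([[0.9, 0.3, 0.1], [0.1, 0.8, 0.1]]), np.array([1, 2]), 0.1)


def test_alpha_zero_full_calibration_coverage():
    rng = np.random.default_rng(11)
    probs = rng.dirichlet(np.ones(3), size=200)
    labels = rng.integers(1, 4, size=200)
    thresholds = estimate_thresholds(probs, labels, 0.0)
    sets = assign_label_sets(probs, thresholds)
    cov = empirical_coverage(sets, labels)
    np.testing.assert_allclose(cov, 1.0)


# ---------------------------------------------------------------- label sets


def test_assign_label_sets_inclusive_and_null():
    thresholds = ThresholdSet(np.array([0.5, 0.5, 0.5]), np.full(3, 0.1), np.full(3, 10))
    probs = np.array(
        [
            [0.5, 0.3, 0.2],  # exactly at threshold -> included (inclusive >=)
            [0.4, 0.35, 0.25],  # nothing reaches 0.5 -> null set
            [0.5, 0.5, 0.0],  # two labels at threshold -> ambiguous pair
        ]
    )
    sets = assign_label_sets(probs, thresholds)
    assert sets.member.tolist() == [
        [True, False, False],
        [False, False, False],
        [True, True, False],
    ]
    assert sets.set_size.tolist() == [1, 0, 2]


def test_assign_label_sets_shape_mismatch():
    thresholds = ThresholdSet(np.array([0.5, 0.5]), np.full(2, 0.1), np.full(2, 10))
    with pytest.raises(ValueError, match="thresholds"):
        assign_label_sets(np.array([[0.3, 0.3, 0.4]]), thresholds)


def test_empirical_coverage_counts_and_missing_class():
    from labelsurv.conformal import LabelSetMatrix

    member = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 0], [0, 1, 0]], dtype=bool)
    labels = np.array([1, 1, 1, 2])
    sets = LabelSetMatrix(member)
    cov = empirical_coverage(sets, labels)
    assert cov[0] == pytest.approx(2 / 3)  # null set never covers
    assert cov[1] == pytest.approx(1.0)
    assert np.isnan(cov[2])  # class 3 unobserved


def test_ambiguity_distribution_sums_to_one():
    from labelsurv.conformal import LabelSetMatrix

    member = np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1], [0, 0, 0]], dtype=bool)
    sets = LabelSetMatrix(member)
    df = ambiguity_distribution(sets, labels=np.array([1, 2, 3, 1]))
    overall = df[df.group == "overall"].set_index("set_size")["proportion"]
    assert overall[0] == overall[1] == overall[2] == overall[3] == pytest.approx(0.25)
    for g, sub in df.groupby("group"):
        assert sub["proportion"].sum() == pytest.approx(1.0)


def test_validate_probabilities_renormalizes_within_tolerance():
    probs = np.array([[0.5, 0.5 + 5e-9]])
    out = validate_probabilities(probs)
    assert out.sum(axis=1) == pytest.approx(1.0, abs=1e-15)


def test_coverage_property_exchangeable_oracle_probabilities():
    """Mean per-class coverage over repetitions is at least 1 - alpha
    (within Monte Carlo error) when labels are drawn from the very
    probabilities fed to the conformal step (exchangeability holds)."""
    alpha, reps = 0.2, 200
    rng = np.random.default_rng(99)
    covs = []
    for _ in range(reps):
        probs_cal = rng.dirichlet((4, 3, 2), size=150)
        y_cal = (probs_cal.cumsum(1) > rng.random((150, 1))).argmax(1) + 1
        if len(np.unique(y_cal)) < 3:
            continue
        probs_val = rng.dirichlet((4, 3, 2), size=300)
        y_val = (probs_val.cumsum(1) > rng.random((300, 1))).argmax(1) + 1
        thresholds = estimate_thresholds(probs_cal, y_cal, alpha)
        covs.append(empirical_coverage(assign_label_sets(probs_val, thresholds), y_val))
    mean_cov = np.nanmean(covs, axis=0)
    mc_sd = np.nanstd(covs, axis=0) / np.sqrt(len(covs))
    assert np.all(mean_cov >= 1 - alpha - 2 * mc_sd)
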