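import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labelsurv import greenwood_ci, km_fit, km_summary, stratified_summaries, survival_bias


def km_oracle(time, event):
    """Hand-rolled product-limit loop, deaths before censorings at ties."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    s, out = 1.0, {}
    for t in np.unique(time[event]):
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & event)
        s *= 1 - d / n_at_risk
        out[float(t)] = s
    return out


# ------------------------------------------------------------------- km_fit


def test_km_no_censoring_steps():
    curve = km_fit(np.array([10.0, 20.0, 30.0]), np.array([True, True, True]))
    np.testing.assert_allclose(curve.event_times, [10, 20, 30])
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])


def test_km_with_censoring():
    # censoring at 20 removes one from the risk set before the event at 30
    curve = km_fit(np.array([10.0, 20.0, 30.0]), np.array([True, False, True]))
    np.testing.assert_allclose(curve.event_times, [10, 30])
    np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])


def test_km_all_censored_flat():
    curve = km_fit(np.array([5.0, 9.0]), np.array([False, False]))
    assert curve.event_times.size == 0
    assert curve.survival_at(100.0) == 1.0


def test_km_errors():
    with pytest.raises(ValueError, match="nonnegative"):
        km_fit(np.array([-1.0]), np.array([True]))
    with pytest.raises(ValueError, match="at least one"):
        km_fit(np.array([]), np.array([]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 60))
def test_km_equals_empirical_survival_without_censoring(seed, n):
    rng = np.random.default_rng(seed)
    time = rng.exponential(50, n).round(1)  # rounding manufactures ties
    curve = km_fit(time, np.ones(n, bool))
    for t in curve.event_times:
        assert curve.survival_at(t) == pytest.approx(np.mean(time > t))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_km_matches_hand_rolled_oracle_with_censoring(seed):
    rng = np.random.default_rng(seed)
    n = 40
    time = rng.exponential(50, n).round(0)
    event = rng.random(n) < 0.7
    if not event.any():
        return
    curve = km_fit(time, event)
    oracle = km_oracle(time, event)
    for t, s in zip(curve.event_times, curve.survival):
        assert s == pytest.approx(oracle[float(t)])


def test_greenwood_variance_hand_computation():
    # n=4, events at 1 and 3, censored at 2, survivor at 4.
    # t=1: n=4 d=1 -> S=3/4, term 1/(4*3)
    # t=3: n=2 d=1 -> S=3/8, term 1/(2*1)
    curve = km_fit(np.array([1.0, 2.0, 3.0, 4.0]), np.array([True, False, True, False]))
    np.testing.assert_allclose(curve.survival, [0.75, 0.375])
    expected = [0.75**2 * (1 / 12), 0.375**2 * (1 / 12 + 1 / 2)]
    np.testing.assert_allclose(curve.greenwood_var, expected)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_greenwood_variance_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = 30
    time = rng.exponential(40, n).round(0)
    event = rng.random(n) < 0.6
    if not event.any():
        return
    curve = km_fit(time, event)
    for i, t in enumerate(curve.event_times):
        acc = 0.0
        for tj in np.unique(time[event]):
            if tj > t:
                continue
            nj = np.sum(time >= tj)
            dj = np.sum((time == tj) & event)
            if nj > dj:
                acc += dj / (nj * (nj - dj))
        expected = curve.survival[i] ** 2 * acc if curve.survival[i] > 0 else 0.0
        assert curve.greenwood_var[i] == pytest.approx(expected)


# --------------------------------------------------------------- summaries


def test_median_and_horizons():
    curve = km_fit(np.array([10.0, 20.0, 30.0, 40.0]), np.ones(4, bool))
    summary = km_summary(curve, horizons=(15.0, 35.0))
    assert summary.median_days == pytest.approx(20.0)  # first time S <= 0.5
    assert summary.horizon_survival[15.0] == pytest.approx(0.75)
    assert summary.horizon_survival[35.0] == pytest.approx(0.25)


def test_median_missing_when_curve_stays_high():
    time = np.array([100.0] * 9 + [5.0])
    event = np.array([False] * 9 + [True])
    summary = km_summary(km_fit(time, event), horizons=(50.0,))
    assert np.isnan(summary.median_days)


def test_exponential_closed_form_median_and_horizon():
    # b = 90, beta = 0: median = 90*ln 2 ~ 62.38 days, S(90) = e^-1
    rng = np.random.default_rng(42)
    n = 100_000
    time = rng.exponential(90, n)
    event = time <= 365
    summary = km_summary(km_fit(np.minimum(time, 365), event), horizons=(90.0,))
    assert summary.median_days == pytest.approx(90 * np.log(2), abs=1.5)
    assert summary.horizon_survival[90.0] == pytest.approx(np.exp(-1), abs=0.01)


def test_greenwood_ci_hand_and_clipping():
    curve = km_fit(np.array([1.0, 2.0, 3.0, 4.0]), np.array([True, False, True, False]))
    lo, hi = greenwood_ci(curve, 1.5, level=0.95)
    se = np.sqrt(0.75**2 / 12)
    assert lo == pytest.approx(0.75 - 1.959963984540054 * se)
    assert hi == pytest.approx(min(1.0, 0.75 + 1.959963984540054 * se))
    # before the first event: S=1, variance 0 -> degenerate interval
    assert greenwood_ci(curve, 0.5) == (1.0, 1.0)
    with pytest.raises(ValueError, match="level"):
        greenwood_ci(curve, 1.5, level=1.5)


def test_stratified_matches_manual_subsets(toy_cohort):
    out = stratified_summaries(toy_cohort.time, toy_cohort.event, toy_cohort.labels, 3)
    for y in (1, 2, 3):
        mask = toy_cohort.labels == y
        direct = km_summary(
            km_fit(toy_cohort.time[mask], toy_cohort.event[mask]), stratum=y
        )
        assert out[y].n == direct.n
        assert out[y].horizon_survival == direct.horizon_survival


def test_stratified_empty_stratum_is_none():
    out = stratified_summaries(
        np.array([1.0, 2.0]), np.array([True, True]), np.array([1, 1]), n_classes=2
    )
    assert out[2] is None


def test_survival_bias_zero_for_identical_strata(toy_cohort):
    obs = stratified_summaries(toy_cohort.time, toy_cohort.event, toy_cohort.labels, 3)
    bias = survival_bias(obs, obs)
    med = bias[bias.quantity == "median_days"]["bias"]
    assert np.nansum(np.abs(med)) == pytest.approx(0.0)
    pp = bias[bias.quantity.str.startswith("surv")]["bias"]
    assert np.nansum(np.abs(pp)) == pytest.approx(0.0)


def test_survival_bias_empty_stratum_reason(toy_cohort):
    obs = stratified_summaries(toy_cohort.time, toy_cohort.event, toy_cohort.labels, 3)
    pred = dict(obs)
    pred[2] = None
    bias = survival_bias(pred, obs)
    row = bias[(bias.stratum == 2)]
    assert (row.reason == "empty_stratum").all()
    assert row.bias.isna().all()
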