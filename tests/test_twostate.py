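"""Kaplan-Meier, Brookmeyer-Crowley median CI, Cox regression, VIF."""

import numpy as np
import pandas as pd
import pytest

from msmpub.records import Status, ValidationError, impute_sample_size
from msmpub.twostate import (
    conditional_published_median,
    cox_fit,
    km_curve_frame,
    km_fit,
    median_ci_brookmeyer_crowley,
    to_survival_sample,
    variance_inflation_factors,
)

from conftest import make_record


def _sample(times, events, covariate=None):
    df = pd.DataFrame({"time": times, "event": events})
    df.insert(0, "study_id", [f"s{i}" for i in range(len(times))])
    if covariate is not None:
        df["x"] = covariate
    return df


# ---------------------------------------------------------------------------
# Survival sample construction

def test_survival_times_from_years():
    published = make_record(approval_year=2000, publication_year=2004, completion_year=2002)
    censored = make_record(
        approval_year=2002, followup_end_year=2010, status=Status.ONGOING,
        completion_year=None, publication_year=None,
    )
    df = to_survival_sample([published, censored])
    assert df.loc[0, "time"] == 4.0 and df.loc[0, "event"] == 1
    assert df.loc[1, "time"] == 8.0 and df.loc[1, "event"] == 0


def test_survival_sample_event_fraction_matches_cohort(fixture_cohort):
    records, truth, _ = fixture_cohort
    records, _, _ = impute_sample_size(records)
    df = to_survival_sample(records)
    realized = (truth.pub_time < truth.horizon).mean()
    assert df["event"].mean() == pytest.approx(realized)


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_hand_product_limit():
    km = km_fit(_sample([1, 2, 3], [1, 1, 1]))
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_allclose(km.times, [1, 2, 3])
    # Greenwood variance at the first event time: S^2 * d/(n(n-d))
    assert km.variance[0] == pytest.approx((2 / 3) ** 2 * (1 / (3 * 2)))


def test_km_all_censored_is_flat_one():
    with pytest.warns(UserWarning, match="no events"):
        km = km_fit(_sample([2, 4, 6], [0, 0, 0]))
    assert len(km.times) == 0
    assert km.survival_at(5.0) == 1.0


def test_km_without_censoring_equals_ecdf():
    rng = np.random.default_rng(4)
    times = rng.integers(1, 10, size=50).astype(float)
    km = km_fit(_sample(times, np.ones(50, dtype=int)))
    for t in np.unique(times):
        assert km.survival_at(t) == pytest.approx(np.mean(times > t))


def test_km_curve_frame_monotone():
    rng = np.random.default_rng(5)
    times = rng.integers(1, 12, size=80).astype(float)
    events = rng.integers(0, 2, size=80)
    events[0] = 1
    frame = km_curve_frame(km_fit(_sample(times, events)))
    s = frame["survival"].to_numpy()
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s >= 0) & (s <= 1))


# ---------------------------------------------------------------------------
# Brookmeyer-Crowley median CI

def test_median_is_first_time_below_half():
    km = km_fit(_sample([1, 2, 3, 4], [1, 1, 1, 1]))
    ci = median_ci_brookmeyer_crowley(km)
    assert ci.median == 2.0
    assert ci.lower <= ci.median <= (ci.upper if np.isfinite(ci.upper) else np.inf)


def test_all_events_at_single_time_degenerate_ci():
    km = km_fit(_sample([5] * 12, [1] * 12))
    ci = median_ci_brookmeyer_crowley(km)
    assert ci.median == 5.0
    assert ci.lower == 5.0 and ci.upper == 5.0


def test_heavy_late_censoring_unbounded_upper():
    """When the survival curve only grazes 1/2 near the end of a staggered
    follow-up, the median interval is one-sided: [finite, +inf)."""
    rng = np.random.default_rng(1234)
    n = 800
    # yearly event times with a median near the end of follow-up, censored
    # administratively at staggered cohort horizons
    t_event = np.floor(rng.exponential(1 / 0.0648, size=n)) + 1
    cens = rng.choice([8.0, 9.0, 11.0], size=n)
    times = np.minimum(t_event, cens)
    events = (t_event <= cens).astype(int)
    km = km_fit(_sample(times, events))
    ci = median_ci_brookmeyer_crowley(km)
    assert np.isfinite(ci.lower)
    assert np.isinf(ci.upper)


@pytest.mark.parametrize("n", [7, 25, 51])
def test_bc_median_equals_sample_median_without_censoring(n):
    rng = np.random.default_rng(n)
    times = np.ceil(rng.exponential(5.0, size=n))
    ci = median_ci_brookmeyer_crowley(km_fit(_sample(times, np.ones(n, dtype=int))))
    assert ci.median == np.median(times)


def test_median_never_reached():
    km = km_fit(_sample([1, 2, 3, 4, 5], [1, 0, 0, 0, 0]))
    ci = median_ci_brookmeyer_crowley(km)
    assert np.isnan(ci.median)
    assert np.isinf(ci.upper)


def test_conditional_published_median_is_descriptive():
    df = _sample([1, 3, 5, 9, 9], [1, 1, 1, 0, 0])
    assert conditional_published_median(df) == 3.0


# ---------------------------------------------------------------------------
# Cox regression

def test_cox_symmetric_groups_hr_one():
    times = [1, 2, 3, 4, 1, 2, 3, 4]
    events = [1, 1, 1, 0, 1, 1, 1, 0]
    x = [0, 0, 0, 0, 1, 1, 1, 1]
    res = cox_fit(_sample(times, events, covariate=x), covariates=("x",))
    assert res.hr_table.iloc[0].hr == pytest.approx(1.0, abs=1e-6)


def _efron_partial_loglik(beta, times, events, x):
    """Brute-force Efron partial log-likelihood for a single covariate."""
    ll = 0.0
    for t in np.unique(np.asarray(times)[np.asarray(events) == 1]):
        d_idx = [i for i in range(len(times)) if times[i] == t and events[i] == 1]
        r_idx = [i for i in range(len(times)) if times[i] >= t]
        d = len(d_idx)
        sum_d = sum(np.exp(beta * x[i]) for i in d_idx)
        sum_r = sum(np.exp(beta * x[i]) for i in r_idx)
        ll += beta * sum(x[i] for i in d_idx)
        for l in range(d):
            ll -= np.log(sum_r - (l / d) * sum_d)
    return ll


def test_cox_matches_brute_force_efron_grid():
    times = [1, 1, 2, 2, 3, 4, 5, 6]
    events = [1, 1, 1, 0, 1, 1, 0, 1]
    x = [1, 0, 1, 1, 0, 1, 0, 0]
    res = cox_fit(_sample(times, events, covariate=x), covariates=("x",))
    grid = np.arange(-3, 3, 1e-4)
    lls = [_efron_partial_loglik(b, times, events, x) for b in grid]
    beta_grid = grid[int(np.argmax(lls))]
    assert res.params.iloc[0] == pytest.approx(beta_grid, abs=1e-4)


def test_cox_invariant_to_time_scaling_and_centering():
    rng = np.random.default_rng(21)
    n = 120
    x = rng.integers(0, 2, size=n).astype(float)
    times = np.ceil(rng.exponential(5 / np.exp(0.7 * x))).astype(float)
    events = (times <= 8).astype(int)
    times = np.minimum(times, 8.0)
    base = cox_fit(_sample(times, events, covariate=x), covariates=("x",))
    scaled = cox_fit(_sample(times * 12.0, events, covariate=x), covariates=("x",))
    centred = cox_fit(_sample(times, events, covariate=x - x.mean()), covariates=("x",))
    assert scaled.params.iloc[0] == pytest.approx(base.params.iloc[0], abs=1e-6)
    assert centred.params.iloc[0] == pytest.approx(base.params.iloc[0], abs=1e-6)


def test_cox_rank_deficiency_drop_and_flag():
    df = _sample([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1], covariate=[1, 0, 1, 0, 1, 0])
    df["constant"] = 1.0
    with pytest.warns(UserWarning, match="rank-deficient"):
        res = cox_fit(df, covariates=("x", "constant"))
    assert res.dropped == ("constant",)
    assert list(res.params.index) == ["x"]
    with pytest.raises(ValidationError, match="no estimable"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cox_fit(df, covariates=("constant",))


def test_cox_requires_events():
    with pytest.raises(ValidationError):
        cox_fit(_sample([1, 2], [0, 0], covariate=[0, 1]), covariates=("x",))


# ---------------------------------------------------------------------------
# VIF

def test_vif_orthogonal_design_is_one():
    cov = np.diag([0.4, 0.9, 2.0])
    np.testing.assert_allclose(variance_inflation_factors(cov), np.ones(3))


def test_vif_two_correlated_coefficients():
    rho = 0.9
    cov = np.array([[1.0, rho], [rho, 1.0]])
    vif = variance_inflation_factors(cov)
    np.testing.assert_allclose(vif, 1 / (1 - rho**2), rtol=1e-12)


def test_vif_singular_matrix_raises():
    cov = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValueError):
        variance_inflation_factors(cov)


def test_vif_on_synthetic_cohort_below_three(fixture_cohort):
    records, _, _ = fixture_cohort
    records, _, _ = impute_sample_size(records)
    sample = to_survival_sample(records)
    res = cox_fit(sample)
    vif = variance_inflation_factors(res.cov)
    assert (vif < 3).all()


# ---------------------------------------------------------------------------
# Attenuation of opposed effects

def test_two_state_hr_attenuated_when_legs_oppose():
    """A covariate speeding completion but slowing publication yields a
    two-state HR closer to the null than either true per-leg effect."""
    import msmpub.simulate as sim
    from msmpub.msm import PiecewiseIntensityModel

    beta = np.zeros((4, 8))
    beta[0, 1] = np.log(2.0)   # RCT completes faster
    beta[2, 1] = np.log(0.5)   # ... but publishes slower once completed
    model = PiecewiseIntensityModel(
        (2.0, 4.0, 7.0, 9.0), sim.DEFAULT_TRUE_LOG_BASELINE.copy(), beta
    )
    scenario = sim.SimulationScenario(
        n_studies=4000, true_model=model, timing_observed_prob=(1.0, 1.0),
        response_prob=1.0, seed=77,
    )
    records, _ = sim.simulate_cohort(scenario)
    records, _, _ = impute_sample_size(records)
    sample = to_survival_sample(records)
    res = cox_fit(sample)
    b2 = res.params["rct"]
    assert abs(b2) < abs(np.log(2.0))
    assert abs(b2) < abs(np.log(0.5))
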