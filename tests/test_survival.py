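"""Response rates, biomarker grouping, KM, log-rank and Cox fits."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from plasmacna.simulate import simulate_survival
from plasmacna.survival import (
    cox_fit,
    dcr,
    dichotomize_median,
    elevated_fraction,
    km_estimate,
    logrank,
    quartile_groups,
)


# ---------------------------------------------------------------- responses

def test_dcr_worked_example():
    """0 CR + 2 PR + 94 SD/nonCRnonPD among 151 subjects -> DCR 63.6%."""
    responses = ["PR"] * 2 + ["SD"] * 60 + ["nonCRnonPD"] * 34 + ["PD"] * 55
    assert len(responses) == 151
    pct, ci = dcr(responses)
    assert round(pct, 1) == 63.6
    assert ci[0] < pct < ci[1]


def test_dcr_extremes_and_errors():
    assert dcr(["PD"] * 5)[0] == 0.0
    assert dcr(["CR"] * 5)[0] == 100.0
    with pytest.raises(ValueError):
        dcr([])
    with pytest.raises(ValueError, match="unknown"):
        dcr(["SD", "WAT"])


def test_elevated_fraction_worked_example():
    """122 of 151 strictly above the healthy 90th percentile -> 80.8%
    (Wald 95% CI 74.5-87.1%)."""
    controls = np.linspace(0.28, 0.54, 14)
    threshold = np.percentile(controls, 90)
    values = np.concatenate([
        np.full(122, threshold + 1.0),
        np.full(29, threshold - 0.1),
    ])
    pct, (lo, hi) = elevated_fraction(values, controls)
    assert round(pct, 1) == 80.8
    assert round(lo, 1) == 74.5
    assert round(hi, 1) == 87.1


def test_elevated_fraction_all_below():
    controls = np.arange(10.0)
    assert elevated_fraction(np.zeros(5), controls)[0] == 0.0


@pytest.mark.parametrize("count,nobs", [(3, 8), (0, 5), (7, 9), (122, 151)])
def test_wald_ci_matches_independent_implementation(count, nobs):
    """The Wald interval agrees with statsmodels' normal-approximation CI."""
    values = np.concatenate([np.ones(count), -np.ones(nobs - count)])
    pct, (lo, hi) = elevated_fraction(values, controls=[0.0, 0.0])
    # statsmodels clips its interval to [0, 1]; ours reports the raw Wald
    # bounds, so compare after clipping
    ref_lo, ref_hi = proportion_confint(count, nobs, method="normal")
    assert np.clip(lo / 100, 0, 1) == pytest.approx(ref_lo, abs=1e-9)
    assert np.clip(hi / 100, 0, 1) == pytest.approx(ref_hi, abs=1e-9)


# ----------------------------------------------------------------- grouping

def test_dichotomize_median_rules():
    labels = dichotomize_median([1, 2, 3, 4])
    assert labels.tolist() == ["low", "low", "high", "high"]
    # a value exactly at the median goes low
    labels = dichotomize_median([1.0, 2.0, 3.0])
    assert labels[1] == "low"


def test_dichotomize_151_distinct_values_splits_76_75():
    rng = np.random.default_rng(6)
    values = rng.permutation(np.arange(151, dtype=float) + rng.uniform(0, .5, 151))
    labels = dichotomize_median(values)
    counts = pd.Series(labels).value_counts()
    assert counts["low"] == 76 and counts["high"] == 75


def test_dichotomize_balance_property():
    rng = np.random.default_rng(7)
    for n in (10, 11, 151, 152):
        values = rng.permutation(np.arange(n, dtype=float))
        labels = dichotomize_median(values)
        n_low = int(np.sum(labels == "low"))
        assert abs(n_low - (n - n_low)) <= 1


def test_quartile_groups_sizes_and_rank_invariance():
    labels = quartile_groups(np.arange(1, 9, dtype=float))
    assert pd.Series(labels).value_counts().tolist() == [2, 2, 2, 2]
    rng = np.random.default_rng(8)
    values = rng.permutation(np.arange(151, dtype=float))
    labels = quartile_groups(values)
    sizes = sorted(pd.Series(labels).value_counts().tolist())
    assert sizes == [37, 38, 38, 38]
    # monotone relabelling leaves groups unchanged
    again = quartile_groups(np.exp(values / 50.0))
    assert (again == labels).all()


def test_grouping_input_validation():
    with pytest.raises(ValueError):
        dichotomize_median([1.0])
    with pytest.raises(ValueError):
        quartile_groups([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------- KM

def _km_oracle(times, events):
    """Brute-force product-limit estimator over the risk sets."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


def test_km_uncensored_steps_and_median():
    res = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
    assert res.median == 3
    oracle = _km_oracle([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
    for t, s in oracle.items():
        idx = np.searchsorted(res.times, t)
        assert res.survival[idx] == pytest.approx(s)


def test_km_all_censored_median_not_reached():
    res = km_estimate([1, 2, 3], [0, 0, 0])
    assert not res.median_reached
    assert np.allclose(res.survival, 1.0)


def test_km_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(9)
    for _ in range(10):
        n = 30
        times = np.round(rng.exponential(5, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        res = km_estimate(times, events)
        for t, s in _km_oracle(times, events).items():
            idx = np.searchsorted(res.times, t)
            assert res.survival[idx] == pytest.approx(s)


def test_km_monotone_and_starts_at_one():
    rng = np.random.default_rng(10)
    times = rng.exponential(5, 50)
    events = rng.integers(0, 2, 50)
    res = km_estimate(times, events)
    assert res.survival[0] <= 1.0 + 1e-12
    assert np.all(np.diff(res.survival) <= 1e-12)
    assert res.times[0] == 0.0 and res.survival[0] == 1.0


# ----------------------------------------------------------------- log-rank

def _logrank_oracle(times, events, groups):
    """Textbook two-group log-rank chi-square via explicit risk tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g1 = np.unique(groups)[0]
    obs1 = exp1 = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g1)).sum()
        obs1 += d1
        exp1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs1 - exp1) ** 2 / var


def test_logrank_zero_for_identical_groups():
    times = [1, 2, 3, 4, 1, 2, 3, 4]
    events = [1, 1, 0, 1] * 2
    groups = ["a"] * 4 + ["b"] * 4
    stat, p = logrank(times, events, groups)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_risk_table_on_six_subjects():
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    events = [1, 1, 1, 1, 1, 1]
    groups = ["a", "a", "a", "b", "b", "b"]
    stat, _ = logrank(times, events, groups)
    assert stat == pytest.approx(_logrank_oracle(times, events, groups),
                                 rel=1e-6)


def test_logrank_matches_oracle_on_random_fixtures():
    rng = np.random.default_rng(13)
    for _ in range(5):
        n = 40
        times = np.round(rng.exponential(5, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        groups = rng.choice(["a", "b"], n)
        if events.sum() == 0 or len(np.unique(groups)) < 2:
            continue
        stat, _ = logrank(times, events, groups)
        assert stat == pytest.approx(_logrank_oracle(times, events, groups),
                                     rel=1e-6)
        # invariant under group relabelling
        flipped = np.where(groups == "a", "b", "a")
        stat2, _ = logrank(times, events, flipped)
        assert stat2 == pytest.approx(stat, rel=1e-9)


def test_logrank_type_i_error_under_null():
    """Under no group effect, p < 0.05 in roughly 5% of simulations."""
    rng = np.random.default_rng(14)
    rejections = 0
    n_sims = 400
    for i in range(n_sims):
        groups = np.array(["low"] * 30 + ["high"] * 30)
        df = simulate_survival(groups, group_hr=1.0, censoring_rate=0.2,
                               seed=rng)
        _, p = logrank(df["os_months"], df["os_event"], groups)
        rejections += p < 0.05
    rate = rejections / n_sims
    mc_se = np.sqrt(0.05 * 0.95 / n_sims)
    assert abs(rate - 0.05) < 2.5 * mc_se + 0.01


def test_logrank_needs_two_groups():
    with pytest.raises(ValueError):
        logrank([1, 2], [1, 1], ["a", "a"])


# --------------------------------------------------------------------- Cox

def _cohort(n=150, hr=3.5, seed=0, censoring=0.3):
    groups = np.array(["low"] * (n // 2) + ["high"] * (n - n // 2))
    df = simulate_survival(groups, group_hr=hr, censoring_rate=censoring,
                           seed=seed)
    df["group_high"] = (groups == "high").astype(int)
    return df


def test_cox_recovers_generating_hr():
    """Two exponential groups with true HR 3.5, n = 150, ~70% events:
    the fitted HR lands in (2.4, 5.2)."""
    df = _cohort(seed=15)
    fit = cox_fit(df, "os", ["group_high"])
    hr = fit.loc["group_high", "hr"]
    assert 2.4 < hr < 5.2
    assert fit.loc["group_high", "ci_low"] < hr < fit.loc["group_high", "ci_high"]


def test_cox_null_covariate_ci_coverage():
    """An independent covariate: HR ~ 1 and the 95% CI covers 1 in >= 93
    of 100 seeded replicates."""
    covered = 0
    hrs = []
    for seed in range(100):
        df = _cohort(hr=1.0, seed=seed, n=120)
        rng = np.random.default_rng(10_000 + seed)
        df["noise"] = rng.normal(size=len(df))
        fit = cox_fit(df, "os", ["noise"])
        lo, hi = fit.loc["noise", "ci_low"], fit.loc["noise", "ci_high"]
        covered += lo <= 1.0 <= hi
        hrs.append(fit.loc["noise", "hr"])
    assert covered >= 93
    assert np.mean(hrs) == pytest.approx(1.0, abs=0.05)


def test_cox_duplicating_subjects_keeps_point_estimate():
    """Duplicating every subject leaves the HR essentially unchanged.

    Duplication turns every event time into a tie, so with Efron tie
    handling the invariance is approximate (exact under Breslow); a 1%
    tolerance covers the Efron adjustment at this sample size.
    """
    df = _cohort(seed=16, n=80)
    fit1 = cox_fit(df, "os", ["group_high"])
    doubled = pd.concat([df, df], ignore_index=True)
    fit2 = cox_fit(doubled, "os", ["group_high"])
    assert fit2.loc["group_high", "hr"] == pytest.approx(
        fit1.loc["group_high", "hr"], rel=0.01)


def test_cox_multivariable_screens_univariable_significant():
    """Only covariates with univariable p < 0.05 enter the joint model."""
    df = _cohort(seed=17)
    rng = np.random.default_rng(18)
    df["noise"] = rng.normal(size=len(df))
    multi = cox_fit(df, "os", ["group_high", "noise"], mode="multivariable")
    assert "group_high" in multi.index
    assert "noise" not in multi.index
    assert (multi["mode"] == "multivariable").all()


def test_cox_input_validation():
    df = _cohort(seed=19, n=20)
    with pytest.raises(ValueError, match="endpoint"):
        cox_fit(df, "pfs", ["group_high"])
    with pytest.raises(ValueError, match="missing column"):
        cox_fit(df, "os", ["nope"])
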