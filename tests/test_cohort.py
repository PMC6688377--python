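"""Cohort sampler distributions against their analytic oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from orthocost import (
    CohortParams,
    LABIAL,
    LINGUAL,
    nb_zero_probability,
    nb_zero_probability_uniform_duration,
    sample_ages,
    sample_defect_counts,
    sample_durations,
    sample_residual_lifetimes,
    simulate_cohort,
)
from conftest import TEST_SEED

N = 200_000
PARAMS = CohortParams(n_sim=N)


def test_ages_uniform_support_and_mean(rng):
    ages = sample_ages(PARAMS, rng)
    assert ages.min() >= 12.0 and ages.max() <= 18.0
    se = 6.0 / math.sqrt(12 * N)  # sd of U(12,18) is 6/sqrt(12)
    assert abs(ages.mean() - 15.0) < 3 * se


def test_durations_uniform_support_mean_and_median(rng):
    dur = sample_durations(PARAMS, rng)
    assert dur.min() >= 9.0 and dur.max() <= 45.0
    se = 36.0 / math.sqrt(12 * N)
    assert abs(dur.mean() - 27.0) < 3 * se
    # half of all treatments finish within the 27-month median
    frac_below = (dur < 27.0).mean()
    assert abs(frac_below - 0.5) < 3 * math.sqrt(0.25 / N)


def test_samplers_are_deterministic_under_a_seed():
    a = simulate_cohort(CohortParams(n_sim=5_000), LABIAL, np.random.default_rng(11))
    b = simulate_cohort(CohortParams(n_sim=5_000), LABIAL, np.random.default_rng(11))
    for field in ("age_start", "tx_duration", "n_wsl", "n_cav", "residual_months"):
        np.testing.assert_array_equal(getattr(a, field), getattr(b, field))


def test_defect_counts_are_bounded_integers(rng):
    dur = sample_durations(PARAMS, rng)
    counts = sample_defect_counts(LABIAL.wsl_rate, LABIAL.wsl_dispersion, dur, 24, rng)
    assert counts.dtype == np.int64
    assert counts.min() >= 0 and counts.max() <= 24


def test_geometric_zero_probability_closed_form(rng):
    # dispersion 1 is the geometric case: P(0) = 1 / (1 + mean)
    dur = np.full(N, 27.0)
    counts = sample_defect_counts(0.0012, 1.0, dur, 24, rng)
    p0 = nb_zero_probability(0.0012 * 27.0, 1.0)
    assert p0 == pytest.approx(1 / 1.0324, rel=1e-12)
    se = math.sqrt(p0 * (1 - p0) / N)
    assert abs((counts == 0).mean() - p0) < 3 * se


@pytest.mark.parametrize(
    "rate, dispersion",
    [
        (LINGUAL.wsl_rate, LINGUAL.wsl_dispersion),
        (LABIAL.wsl_rate, LABIAL.wsl_dispersion),
        (LINGUAL.cav_rate, LINGUAL.cav_dispersion),
        (LABIAL.cav_rate, LABIAL.cav_dispersion),
    ],
)
def test_zero_fraction_matches_integrated_oracle(rng, rate, dispersion):
    """Empirical defect-free fraction vs the NB closed form averaged over
    the uniform treatment-duration distribution."""
    dur = sample_durations(PARAMS, rng)
    counts = sample_defect_counts(rate, dispersion, dur, 24, rng)
    p0 = nb_zero_probability_uniform_duration(rate, dispersion, 9.0, 45.0)
    se = math.sqrt(p0 * (1 - p0) / N)
    assert abs((counts == 0).mean() - p0) < 3 * se


def test_integrated_zero_probability_frozen_value():
    # labial WSL parameters over U(9,45): quadrature of the closed form
    assert nb_zero_probability_uniform_duration(0.1537, 0.72) == pytest.approx(
        0.272815, abs=5e-6
    )


def test_capped_mean_below_uncapped_mean(rng):
    dur = sample_durations(PARAMS, rng)
    counts = sample_defect_counts(LABIAL.wsl_rate, LABIAL.wsl_dispersion, dur, 24, rng)
    assert counts.mean() < LABIAL.wsl_rate * 27.0


def test_nb_converges_to_poisson_at_large_dispersion(rng):
    """At dispersion 10^6 the count law is indistinguishable from
    Poisson(rate * duration) on a fixed duration."""
    mu = LABIAL.wsl_rate * 27.0
    counts = sample_defect_counts(
        LABIAL.wsl_rate, 1e6, np.full(N, 27.0), 24, rng
    )
    kmax = 15
    observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    expected = stats.poisson.pmf(np.arange(kmax), mu)
    expected = np.append(expected, stats.poisson.sf(kmax - 1, mu)) * N
    _, p = stats.chisquare(observed, expected)
    assert p > 1e-3


def test_nb_zero_probability_domain():
    assert nb_zero_probability(0.0, 0.3) == 1.0
    with pytest.raises(ValueError):
        nb_zero_probability(-1.0, 0.3)
    with pytest.raises(ValueError):
        nb_zero_probability(1.0, 0.0)
    with pytest.raises(ValueError):
        sample_defect_counts(0.0, 1.0, np.ones(3), 24, np.random.default_rng(0))


def test_residual_lifetime_median_and_support(rng):
    resid = sample_residual_lifetimes(PARAMS, np.full(N, 15.0), rng)
    assert resid.min() >= 0.0
    assert resid.max() <= (100.0 - 15.0) * 12.0
    # the age-100 cap binds only in the upper tail, the median is untouched
    se_med = 1.2533 * (696 / math.log(2)) / math.sqrt(N)
    assert abs(np.median(resid) - 696.0) < 3 * se_med


def test_residual_lifetime_cap_edge_cases(rng):
    assert sample_residual_lifetimes(PARAMS, np.array([100.0]), rng)[0] == 0.0
    with pytest.raises(ValueError):
        sample_residual_lifetimes(PARAMS, np.array([100.5]), rng)


def test_residual_lifetime_memorylessness(rng):
    """P(T > a+b | T > a) = P(T > b) for the uncapped exponential draws."""
    params = CohortParams(n_sim=N, median_residual=696.0, max_age=10_000.0)
    t = sample_residual_lifetimes(params, np.full(N, 15.0), rng)
    a, b = 500.0, 300.0
    lhs = (t > a + b).sum() / (t > a).sum()
    rhs = (t > b).mean()
    se = math.sqrt(rhs * (1 - rhs) / (t > a).sum()) * 2  # conservative
    assert abs(lhs - rhs) < 3 * se


def test_cohort_age_plus_duration_plus_residual_capped(rng):
    cohort = simulate_cohort(PARAMS, LABIAL, rng)
    total_months = (
        cohort.age_start * 12 + cohort.tx_duration + cohort.residual_months
    )
    assert (total_months <= 100 * 12 + 1e-9).all()
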