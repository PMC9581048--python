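"""Bayes factors, correlation posteriors, candidate fits and WAIC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cyton2.bayes import (DegenerateDataError, bayes_factor_correlation,
                          classify_bf, compare_candidates,
                          correlation_posterior, fit_candidate,
                          log_bf10_correlation, waic_difference,
                          waic_from_loglik)
from cyton2.distributions import make_distribution


def oracle_bf10(r, n):
    """Direct quadrature of the correlation Bayes-factor integrand,
    independent of the package's log-space implementation."""
    val, _ = quad(lambda rho: (1 - rho**2) ** ((n - 1) / 2)
                  / (1 - rho * r) ** (n - 1.5), -1, 1, limit=200)
    return 0.5 * val


def test_bf_anchor_r0_n3():
    bf10, bf01 = bayes_factor_correlation(0.0, 3)
    assert bf10 == pytest.approx(2 / 3, abs=1e-6)
    assert bf01 == pytest.approx(1.5, abs=1e-6)
    assert bf10 == pytest.approx(oracle_bf10(0.0, 3), abs=1e-8)


@pytest.mark.parametrize("r,n", [(0.3, 10), (0.6, 34), (0.9, 20),
                                 (0.2, 500)])
def test_bf_matches_oracle_quadrature(r, n):
    bf10, _ = bayes_factor_correlation(r, n)
    assert bf10 == pytest.approx(oracle_bf10(r, n), rel=1e-6)


@pytest.mark.parametrize("r", [0.2, 0.5, 0.8])
def test_bf_symmetry_in_r(r):
    assert bayes_factor_correlation(r, 25)[0] == pytest.approx(
        bayes_factor_correlation(-r, 25)[0], rel=1e-9)


def test_bf_increases_with_r_at_fixed_n():
    vals = [bayes_factor_correlation(r, 34)[0] for r in (0.0, 0.3, 0.6)]
    assert vals[0] < vals[1] < vals[2]


def test_bf_at_r0_favours_null_more_with_larger_n():
    bf01s = [bayes_factor_correlation(0.0, n)[1] for n in (10, 100, 1000)]
    assert bf01s[0] < bf01s[1] < bf01s[2]
    assert bf01s[-1] > 1


def test_bf_degenerate_r_raises():
    with pytest.raises(DegenerateDataError):
        bayes_factor_correlation(1.0, 10)


def test_bf_large_n_stays_finite_in_log_space():
    # sharply peaked integrand; the log-space value must stay usable
    log10 = log_bf10_correlation(0.4, 100_000)
    assert np.isfinite(log10) and log10 > 100


# -- classification -----------------------------------------------------

@pytest.mark.parametrize("bf,label", [
    (150, "Extreme"), (5, "Moderate"), (1, "No evidence"),
    (2, "Anecdotal"), (15, "Strong"), (50, "Very strong"),
    (1 / 150, "Extreme"), (0.2, "Moderate"),
])
def test_classify_bf_bands(bf, label):
    assert classify_bf(bf) == label


def test_classify_bf_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_bf(0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(1e-6, 1e6))
def test_classify_bf_partitions_positive_reals(bf):
    label = classify_bf(bf)
    assert label in {"No evidence", "Anecdotal", "Moderate", "Strong",
                     "Very strong", "Extreme"}


# -- correlation posterior ----------------------------------------------

@pytest.fixture(scope="module")
def correlated_pairs():
    rng = np.random.default_rng(12)
    x = rng.normal(50, 10, 200)
    y = 60 + 0.9 * (x - 50) + np.sqrt(1 - 0.81) * rng.normal(0, 10, 200)
    return x, y


def test_correlation_posterior_recovers_strong_rho(correlated_pairs):
    res = correlation_posterior(*correlated_pairs, seed=1)
    assert res.converged
    assert 0.80 <= res.rho_median <= 0.96
    lo, hi = res.rho_ci
    assert lo > 0
    # with uninformative priors the point estimate tracks the sample r
    assert res.rho_median == pytest.approx(res.r, abs=0.05)


def test_correlation_posterior_null_case():
    rng = np.random.default_rng(3)
    x = rng.normal(50, 10, 200)
    y = rng.normal(60, 12, 200)
    res = correlation_posterior(x, y, seed=2)
    lo, hi = res.rho_ci
    assert lo < 0 < hi


def test_correlation_posterior_degenerate_input():
    x = np.arange(20.0)
    with pytest.raises(DegenerateDataError):
        correlation_posterior(x, x, seed=0)
    with pytest.raises(DegenerateDataError):
        correlation_posterior(x, np.full(20, 7.0), seed=0)


def test_density_ellipse_contains_centre(correlated_pairs):
    res = correlation_posterior(*correlated_pairs, seed=1)
    ring = res.density_ellipse(0.95)
    mx, my = res.summary["mu_x"][0], res.summary["mu_y"][0]
    assert ring.shape[1] == 2
    assert ring[:, 0].min() < mx < ring[:, 0].max()
    assert ring[:, 1].min() < my < ring[:, 1].max()


# -- candidate fits ------------------------------------------------------

def test_lognormal_candidate_recovery():
    z = make_distribution("lognormal", m=40, s=0.3).sample(500, seed=3)
    res = fit_candidate(z, "lognormal", seed=4)
    assert res.converged
    assert 36 <= res.posterior_median()["m"] <= 44


def test_delayed_shift_posterior_below_sample_minimum():
    z = make_distribution("delayed_exponential", lam=0.2, c=25).sample(
        300, seed=5)
    res = fit_candidate(z, "delayed_exponential", seed=6)
    assert np.all(res.samples[:, 1] <= z.min())


def test_tiny_spread_data_is_handled():
    z = make_distribution("lognormal", m=40, s=0.01).sample(100, seed=7)
    res = fit_candidate(z, "lognormal", seed=8)
    assert res.posterior_median()["s"] < 0.05


def test_cdf_band_brackets_truth():
    d = make_distribution("lognormal", m=40, s=0.3)
    z = d.sample(400, seed=9)
    res = fit_candidate(z, "lognormal", seed=10)
    grid = np.linspace(10, 120, 30)
    lo, hi = res.cdf_band(grid, n_draws=2000, seed=11)
    truth = d.cdf(grid)
    assert (np.mean((truth >= lo) & (truth <= hi))) > 0.9


# -- WAIC ----------------------------------------------------------------

def test_waic_degenerate_posterior_has_zero_penalty():
    rng = np.random.default_rng(0)
    ll_row = rng.normal(-3, 1, size=25)
    loglik = np.tile(ll_row, (4, 1))        # identical repeated draws
    res = waic_from_loglik(loglik)
    assert res.penalty == pytest.approx(0.0, abs=1e-12)
    assert res.waic == pytest.approx(-2 * ll_row.sum())
    assert res.deviance == pytest.approx(res.waic)


def test_waic_brute_force_tiny_case():
    # n=5 observations, S=3 draws: recompute by hand
    rng = np.random.default_rng(1)
    loglik = rng.normal(-2, 0.5, size=(3, 5))
    res = waic_from_loglik(loglik)
    lppd_i = np.log(np.exp(loglik).mean(axis=0))
    p_i = loglik.var(axis=0, ddof=1)
    waic_i = -2 * (lppd_i - p_i)
    assert np.allclose(res.pointwise, waic_i)
    assert res.waic == pytest.approx(waic_i.sum())
    assert res.se == pytest.approx(np.sqrt(5 * waic_i.var(ddof=1)))
    assert res.pointwise.sum() == pytest.approx(res.waic)


def test_waic_matches_arviz_reference():
    import arviz as az
    rng = np.random.default_rng(2)
    loglik = rng.normal(-2, 0.3, size=(400, 50))
    ours = waic_from_loglik(loglik)
    idata = az.from_dict(
        posterior={"dummy": rng.normal(size=(1, 400))},
        log_likelihood={"z": loglik[None, :, :]})
    ref = az.waic(idata, scale="deviance")
    # identical lppd; the penalty differs only by the S/(S-1) variance
    # convention (this package uses the 1/(S-1) sample variance)
    assert ours.deviance == pytest.approx(
        float(ref.elpd_waic) - 2 * float(ref.p_waic), rel=1e-9)
    assert ours.penalty == pytest.approx(float(ref.p_waic) * 400 / 399,
                                         rel=1e-9)
    assert ours.waic == pytest.approx(float(ref.elpd_waic), rel=1e-3)


def test_waic_difference_identities():
    rng = np.random.default_rng(3)
    a = waic_from_loglik(rng.normal(-2, 0.3, size=(50, 30)))
    d, se = waic_difference(a, a)
    assert d == 0.0 and se == 0.0
    b = waic_from_loglik(rng.normal(-2, 0.3, size=(50, 20)))
    with pytest.raises(ValueError, match="different data sizes"):
        waic_difference(a, b)


def test_waic_ranking_prefers_generating_family():
    z = make_distribution("lognormal", m=40, s=0.3).sample(200, seed=20)
    table = compare_candidates(z, ["lognormal", "delayed_exponential"],
                               seed=21)
    assert table.family.iloc[0] == "lognormal"
    assert table.delta_waic.iloc[1] > 0
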