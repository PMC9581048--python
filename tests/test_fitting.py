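"""Model fitting: cost function, recovery, bootstrap, joint fits, ablation."""

import numpy as np
import pandas as pd
import pytest

from cyton2.fitting import (FitConfig, GenerationCountTable,
                            NegativeVarianceError, ablation_study,
                            bootstrap_ci, count_free_parameters,
                            enumerate_timepoint_removals, fit, joint_fit,
                            params_to_theta, predict_combined, rss,
                            theta_to_params)
from cyton2.synthetic import b_cell_like_parameters, synthesize_counts

QUICK = FitConfig(n_starts=8, seed=0)


@pytest.fixture(scope="module")
def truth():
    return b_cell_like_parameters()


@pytest.fixture(scope="module")
def noiseless(truth):
    return synthesize_counts(truth, noise_sd=0.0, seed=1)


@pytest.fixture(scope="module")
def noisy(truth):
    return synthesize_counts(truth, noise_sd=0.05, seed=1)


# -- data container -----------------------------------------------------

def test_table_validation():
    base = pd.DataFrame({"time_h": [0.0, 0.0], "replicate": [0, 0],
                         "generation": [0, 1], "count": [5.0, 0.0]})
    GenerationCountTable(base)
    with pytest.raises(ValueError, match="negative counts"):
        GenerationCountTable(base.assign(count=[-1.0, 0.0]))
    dup = pd.concat([base, base.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        GenerationCountTable(dup)
    with pytest.raises(ValueError, match="missing columns"):
        GenerationCountTable(base.drop(columns=["count"]))


def test_n0_from_earliest_time(noiseless, truth):
    # noiseless counts at t=0 sum to the generating founder count
    assert noiseless.n0 == pytest.approx(truth.n0, rel=1e-9)


# -- cost ---------------------------------------------------------------

def test_rss_zero_at_generating_parameters(truth, noiseless):
    assert rss(truth, noiseless) == pytest.approx(0.0, abs=1e-9)


def test_rss_single_record_arithmetic(point_mass_params):
    from cyton2.mean_model import CytonParameters
    params = CytonParameters(
        dist_div0=point_mass_params.dist_div0, subsequent=10.0,
        dist_dd=point_mass_params.dist_dd,
        dist_die=point_mass_params.dist_die, n0=4.0)
    # model predicts 8 generation-1 cells at t=45 (n0=4, one division)
    table = GenerationCountTable(pd.DataFrame(
        {"time_h": [45.0], "replicate": [0], "generation": [1],
         "count": [10.0]}))
    assert rss(params, table) == pytest.approx(4.0)


def test_rss_increases_under_perturbation(truth, noiseless):
    base = rss(truth, noiseless)
    theta = params_to_theta(truth)
    for i in range(7):
        bumped = theta.copy()
        bumped[i] *= 1.2
        p = theta_to_params(bumped, "lognormal", truth.n0)
        assert rss(p, noiseless) > base + 1e-3


# -- single-condition fit ----------------------------------------------

def test_fit_finds_global_optimum_on_noiseless_data(truth, noiseless):
    res = fit(noiseless, QUICK)
    assert res.rss <= rss(truth, noiseless) + 1e-6
    assert res.rss == res.start_rss.min()
    assert res.n_free_parameters == 7


def test_fit_recovers_generating_parameters(truth, noisy):
    res = fit(noisy, QUICK)
    rel = np.abs(res.theta - params_to_theta(truth)) / params_to_theta(truth)
    assert np.all(rel < 0.10)


def test_fit_invariant_to_record_order(noisy):
    shuffled = GenerationCountTable(
        noisy.frame.sample(frac=1, random_state=4).reset_index(drop=True))
    a = fit(noisy, QUICK)
    b = fit(shuffled, QUICK)
    assert np.allclose(a.theta, b.theta)
    assert a.rss == pytest.approx(b.rss)


def test_fit_deterministic_given_seed(noisy):
    a = fit(noisy, QUICK)
    b = fit(noisy, QUICK)
    assert np.array_equal(a.theta, b.theta)
    assert np.array_equal(a.start_rss, b.start_rss)


def test_fit_requires_three_timepoints(truth):
    tiny = synthesize_counts(truth, times=[0.0, 48.0], noise_sd=0.0, seed=0)
    with pytest.raises(ValueError, match="3 time points"):
        fit(tiny, QUICK)


# -- bootstrap ----------------------------------------------------------

def test_bootstrap_collapses_on_noiseless_data(truth, noiseless):
    res = fit(noiseless, QUICK)
    boot = bootstrap_ci(noiseless, res, B=20, seed=3)
    for name, (lo, hi) in boot.ci.items():
        width = hi - lo
        assert width < 0.01 * res.params[name]
    assert boot.n_failed == 0


def test_bootstrap_requires_two_resamples(truth, noiseless):
    res = fit(noiseless, QUICK)
    with pytest.raises(ValueError):
        bootstrap_ci(noiseless, res, B=1)


def test_bootstrap_bands_track_true_mean_curve(truth, noisy):
    """The 95% band is a confidence band for the mean curve: it should
    bracket the generating expectation at most observed times (percentile
    bootstrap under-covers somewhat at this noise level)."""
    from cyton2.mean_model import expected_timecourse
    res = fit(noisy, QUICK)
    boot = bootstrap_ci(noisy, res, B=100, seed=5, band_times=noisy.times)
    true_total = expected_timecourse(truth, noisy.times, max_generation=8,
                                     truncation_tol=np.inf).total
    lo, hi = boot.total_band
    covered = (true_total >= lo - 1e-9) & (true_total <= hi + 1e-9)
    assert covered.mean() >= 0.6
    # band widths stay a small fraction of the signal
    peak = true_total.max()
    assert np.all((hi - lo) < 0.25 * peak)


# -- joint fits and combined prediction ---------------------------------

def test_joint_fit_single_condition_degenerates_to_fit(noiseless):
    res = joint_fit({"only": noiseless}, shared=("m",),
                    config=FitConfig(n_starts=8, seed=0))
    assert res.fits["only"].rss == pytest.approx(0.0, abs=1e-6)
    assert res.shared_values["m"] == pytest.approx(10.0, rel=1e-3)


def test_joint_fit_rejects_unknown_shared_name(noiseless):
    with pytest.raises(ValueError, match="not a model parameter"):
        joint_fit({"a": noiseless, "b": noiseless}, shared=("bogus",))


def test_predict_combined_arithmetic():
    def normal_fit(mu0, s0, mudd, sdd, mudie, sdie, m=12.0):
        from cyton2.fitting import FitResult, _NORMAL_NAMES
        theta = np.array([mu0, s0, mudd, sdd, mudie, sdie, m])
        return FitResult(family="normal", param_names=_NORMAL_NAMES,
                         theta=theta, rss=0.0, n0=1000.0,
                         start_rss=np.zeros(1),
                         start_thetas=theta[None, :])
    base = normal_fit(60, 5, 60, 5, 100, 10)
    d27 = normal_fit(66, 6, 66, 6, 100, 10)
    d28 = normal_fit(63, 5, 63, 5, 100, 10)
    pred = predict_combined(base, d27, d28)
    assert pred.dist_dd.params["mu"] == pytest.approx(69.0)
    assert pred.dist_dd.params["sigma"] ** 2 == pytest.approx(36.0)
    # shrinking deltas can push the combined variance negative
    shrink = normal_fit(60, 1, 60, 1, 100, 1)
    with pytest.raises(NegativeVarianceError):
        predict_combined(base, shrink, shrink)
    floored = predict_combined(base, shrink, shrink, variance_floor=0.25)
    assert floored.dist_dd.params["sigma"] == pytest.approx(0.5)


# -- parameter counting and the ablation machinery ----------------------

@pytest.mark.parametrize("kwargs,expected", [
    (dict(), 7),
    (dict(n_conditions=3, shared=("m",)), 19),
    (dict(n_conditions=3), 21),
    (dict(model="full", generations=3), 12),
    (dict(model="full", generations=8), 22),
])
def test_count_free_parameters(kwargs, expected):
    assert count_free_parameters(**kwargs) == expected


def test_enumerate_timepoint_removals_counts():
    assert len(enumerate_timepoint_removals(9)) == 366
    assert len(enumerate_timepoint_removals(4)) == 4
    assert len(enumerate_timepoint_removals(3)) == 0


def test_enumerate_timepoint_removals_rules():
    cases = enumerate_timepoint_removals(9)
    assert len(set(cases)) == len(cases)
    for case in cases:
        assert 1 <= len(case) <= 6              # at least 3 retained
        assert not (0 in case and 1 in case)    # an anchor must survive


def test_ablation_no_removal_noiseless_rmse_zero(noiseless):
    res = ablation_study(noiseless, (), n_synthetic=3, replicates=3,
                         seed=0, config=FitConfig(n_starts=10, seed=0))
    assert res.n_failed == 0
    assert np.median(res.rmse) < 1e-3
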