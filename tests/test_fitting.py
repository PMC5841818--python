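"""Error function, hypothesis fits, ensembles and ratio statistics."""
from dataclasses import replace

import numpy as np
import pytest

from fuelswitch.fitting import (
    FitResult,
    ObservationSet,
    activity_ratio_histograms,
    build_ensemble,
    error_function,
    evaluate_factors,
    fit_activities,
    ratio_summary,
)
from fuelswitch.pipeline import run_protocol
from fuelswitch.synthetic_data import LCR_LIKE, make_ground_truth_pair, make_observations


@pytest.fixture(scope="module")
def short_traj(ref, hcr_demand):
    traj = run_protocol(ref, hcr_demand, 10.0)
    assert traj.status == "ok"
    return traj


def obs_from_traj(traj, times, offsets=0.0, sigma=1.0):
    """Build an observation set from a trajectory's own JO2 series."""
    model = np.interp(times, traj.times, traj.jo2)
    values = model + offsets
    var = np.full_like(np.asarray(times, dtype=float), sigma**2)
    return ObservationSet(times=np.asarray(times, dtype=float),
                          series={"JO2": (values, var)})


def test_error_zero_when_model_equals_data(short_traj):
    obs = obs_from_traj(short_traj, [0.0, 4.0, 8.0])
    assert error_function(short_traj, obs) == 0.0


def test_error_is_mean_standardized_square(short_traj):
    sigma = 2.5e-4
    obs1 = obs_from_traj(short_traj, [5.0], offsets=sigma, sigma=sigma)
    assert error_function(short_traj, obs1) == pytest.approx(1.0, rel=1e-9)
    obs2 = obs_from_traj(short_traj, np.array([2.0, 6.0]),
                         offsets=np.array([sigma, 2 * sigma]), sigma=sigma)
    assert error_function(short_traj, obs2) == pytest.approx(2.5, rel=1e-9)


def test_observation_set_rejects_nonpositive_variance():
    with pytest.raises(ValueError, match="variance"):
        ObservationSet(times=np.array([0.0]),
                       series={"JO2": (np.array([1.0]), np.array([0.0]))})


def test_rq_series_can_be_excluded(short_traj):
    t = np.array([0.0, 5.0])
    rq = np.interp(t, short_traj.times, short_traj.jco2) / np.interp(
        t, short_traj.times, short_traj.jo2
    )
    obs = ObservationSet(
        times=t,
        series={"RQ": (rq + 0.1, np.full(2, 1e-4))},
    )
    assert error_function(short_traj, obs) > 0
    assert error_function(short_traj, obs, include_rq=False) == 0.0


@pytest.fixture(scope="module")
def lcr_obs(ref, lcr_demand):
    _, lcr = make_ground_truth_pair(ref.net, ref.conc0, ref.X_rest)
    return make_observations(ref, lcr, lcr_demand, replace(LCR_LIKE, seed=12)), lcr


def test_single_factor_fits_and_ordering(ref, lcr_demand, lcr_obs):
    """The combined minimal hypothesis beats both single-mechanism fits."""
    obs, lcr = lcr_obs
    fit_mito = fit_activities(ref, obs, lcr_demand, mode="mito_scale_only", seed=1)
    fit_fao = fit_activities(ref, obs, lcr_demand, mode="fao_scale_only", seed=1)
    fit_min = fit_activities(ref, obs, lcr_demand, mode="minimal_combined", seed=1)
    assert fit_min.error < fit_mito.error
    assert fit_min.error < fit_fao.error
    # the two-factor fit recovers the generating transform within a factor of 2
    assert 0.25 <= fit_min.scale_factors["mito_fraction"] <= 1.0
    assert 2.5 <= fit_min.scale_factors["fa_transport_factor"] <= 10.0


def test_free_fit_is_seed_deterministic(ref, lcr_demand, lcr_obs):
    obs, _ = lcr_obs
    kwargs = dict(mode="free_fit", seed=7, n_anneal=6, n_polish=0)
    f1 = fit_activities(ref, obs, lcr_demand, **kwargs)
    f2 = fit_activities(ref, obs, lcr_demand, **kwargs)
    assert f1.error == f2.error
    assert f1.X_fit == f2.X_fit


def test_free_fit_never_returns_worse_than_start(ref, lcr_demand, lcr_obs):
    obs, _ = lcr_obs
    start, _ = evaluate_factors(ref, obs, lcr_demand, None)
    fit = fit_activities(ref, obs, lcr_demand, mode="free_fit", seed=3,
                         n_anneal=10, n_polish=10)
    assert fit.error <= start + 1e-12


def test_ensemble_acceptance_extremes(ref, lcr_demand, lcr_obs):
    obs, lcr = lcr_obs
    err, _ = evaluate_factors(ref, obs, lcr_demand, lcr.factors)
    base = FitResult(X_fit=dict(ref.X_rest), factors=dict(lcr.factors),
                     error=err, mode="minimal_combined", scale_factors={})
    # infinite threshold accepts everything
    ens, rate = build_ensemble(ref, obs, lcr_demand, base, n_sets=3,
                               accept_threshold=np.inf, perturbation=0.05, seed=1)
    assert rate == 1.0 and len(ens) == 3
    # zero perturbation at the exact threshold yields copies
    ens0, rate0 = build_ensemble(ref, obs, lcr_demand, base, n_sets=2,
                                 accept_threshold=err, perturbation=0.0, seed=1)
    assert rate0 == 1.0
    assert ens0[0] == ens0[1]


def test_ratio_histogram_counting():
    a = [{"R": 2.0}] * 3
    b = [{"R": 1.0}] * 3
    ratios = activity_ratio_histograms(a, b)
    assert len(ratios["R"]) == 9
    np.testing.assert_allclose(ratios["R"], 2.0)
    single = activity_ratio_histograms([{"R": 5.0}], [{"R": 5.0}])
    np.testing.assert_allclose(single["R"], 1.0)
    with pytest.raises(ValueError):
        activity_ratio_histograms([], b)
    summary = ratio_summary(ratios)
    assert summary.loc["R", "median"] == pytest.approx(2.0)


def test_phenotype_ratio_medians_concentrate_on_fa_transport(ref, lcr_demand, lcr_obs):
    """HCR/LCR exercise-activity ratios peak on the FA import machinery."""
    obs, lcr = lcr_obs
    err, _ = evaluate_factors(ref, obs, lcr_demand, lcr.factors)
    base_h = FitResult(X_fit=dict(ref.X_rest), factors={}, error=1.0,
                       mode="free_fit", scale_factors={})
    base_l = FitResult(X_fit=dict(ref.X_rest), factors=dict(lcr.factors),
                       error=err, mode="minimal_combined", scale_factors={})
    ens_h = [
        {r: x * ref.headroom for r, x in base_h.X_fit.items()}
    ]
    ens_l = [
        {r: x * ref.headroom * lcr.factors.get(r, 1.0) for r, x in base_l.X_fit.items()}
    ]
    ratios = activity_ratio_histograms(ens_h, ens_l)
    med = {r: float(np.median(v)) for r, v in ratios.items()}
    fa_transport = {"CPT1", "PCT", "CPT2"}
    top = sorted(med, key=med.get, reverse=True)[:3]
    assert set(top) == fa_transport
    assert med["HK"] == pytest.approx(1.0)
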