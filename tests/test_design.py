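"""Hierarchical posterior and two-stage design machinery."""

import numpy as np
import pytest
from numpy.random import default_rng
from scipy.stats import beta, binom

from neobasket.design import (
    CohortData,
    DesignSpec,
    ExceedanceCache,
    HierarchicalPrior,
    QuadratureSettings,
    calibrate_gamma,
    operating_characteristics,
    posterior,
    probability_of_success,
    simulate_trial,
    stage1_go,
)
from neobasket.design import _quadrature_posterior

WIDE = HierarchicalPrior(mu_sd=1e4, tau_scale=1e4)
TRIAL_DATA = (CohortData(8, 14), CohortData(6, 8))
NULLS = (0.03, 0.10)


def test_published_design_parameters(published_design):
    colon, rectum = published_design.cohorts
    assert (colon.p_null, colon.p_alt, colon.n_stage1, colon.n_total) == (0.03, 0.15, 11, 28)
    assert (rectum.p_null, rectum.p_alt, rectum.n_stage1, rectum.n_total) == (0.10, 0.35, 8, 16)
    assert (colon.go_min_responders, rectum.go_min_responders) == (3, 4)
    assert published_design.alpha == 0.05


@pytest.mark.parametrize(
    "x_colon,x_rectum,expected",
    [(3, 4, True), (2, 8, False), (11, 8, True), (3, 3, False), (0, 0, False)],
)
def test_stage1_go_literal_rule(published_design, x_colon, x_rectum, expected):
    stage1 = (CohortData(x_colon, 11), CohortData(x_rectum, 8))
    assert stage1_go(stage1, published_design) is expected


def test_trial_data_exceedance_is_near_one():
    ps = posterior(TRIAL_DATA, NULLS)
    assert ps.exceedance["colon"] > 0.99
    assert ps.exceedance["rectum"] > 0.99
    assert 0 <= ps.p_ci["colon"][0] <= ps.p_mean["colon"] <= ps.p_ci["colon"][1] <= 1


def test_no_responders_gives_low_exceedance():
    ps = posterior((CohortData(0, 14), CohortData(0, 8)), NULLS)
    assert ps.exceedance["colon"] < 0.5
    assert ps.exceedance["rectum"] < 0.5


@pytest.mark.parametrize("x,n,p0", [(5, 14, 0.15), (2, 14, 0.30), (1, 8, 0.10)])
def test_single_cohort_reduction_matches_conjugate_oracle(x, n, p0):
    """Very diffuse hyperpriors with an empty partner cohort reduce to a
    flat prior on delta, i.e. the Haldane-prior conjugate posterior
    Beta(x, n - x) on the response rate."""
    ps = posterior((CohortData(x, n), CohortData(0, 0)), (p0, 0.10), prior=WIDE)
    assert ps.exceedance["colon"] == pytest.approx(float(beta.sf(p0, x, n - x)), abs=0.01)


def test_complete_pooling_limit_equalizes_exceedance():
    tiny = HierarchicalPrior(tau_scale=1e-3)
    ps = posterior((CohortData(8, 14), CohortData(2, 8)), NULLS, prior=tiny)
    assert ps.exceedance["colon"] == pytest.approx(ps.exceedance["rectum"], abs=1e-4)


def test_large_tau_limit_recovers_independent_analyses():
    joint = posterior(TRIAL_DATA, NULLS, prior=WIDE)
    for j, name in enumerate(("colon", "rectum")):
        solo_data = [CohortData(0, 0), CohortData(0, 0)]
        solo_data[j] = TRIAL_DATA[j]
        solo = posterior(tuple(solo_data), NULLS, prior=WIDE)
        assert joint.exceedance[name] == pytest.approx(solo.exceedance[name], abs=0.01)


def test_borrowing_brackets_posterior_mean():
    """With both cohorts above their nulls, the hierarchical posterior mean
    of each response rate lies between the no-pooling and complete-pooling
    means."""
    default = posterior(TRIAL_DATA, NULLS)
    indep = posterior(TRIAL_DATA, NULLS, prior=WIDE)
    pooled = posterior(TRIAL_DATA, NULLS, prior=HierarchicalPrior(tau_scale=1e-3))
    for name in ("colon", "rectum"):
        lo, hi = sorted((indep.p_mean[name], pooled.p_mean[name]))
        assert lo - 0.005 <= default.p_mean[name] <= hi + 0.005


def test_exceedance_monotone_in_responders():
    values = [
        posterior((CohortData(x, 14), CohortData(6, 8)), NULLS).exceedance["colon"]
        for x in (0, 1, 3, 6, 10, 14)
    ]
    assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))


def test_quadrature_resolution_stability():
    s = QuadratureSettings()
    r1 = _quadrature_posterior(TRIAL_DATA, NULLS, HierarchicalPrior(), s)
    r2 = _quadrature_posterior(TRIAL_DATA, NULLS, HierarchicalPrior(), s.doubled())
    assert abs(r1["exceed_0"] - r2["exceed_0"]) < 1e-3
    assert abs(r1["exceed_1"] - r2["exceed_1"]) < 1e-3


def test_quadrature_and_mcmc_agree_on_trial_data():
    quad = posterior(TRIAL_DATA, NULLS)
    mc = posterior(TRIAL_DATA, NULLS, method="mcmc", seed=20240901)
    for name in ("colon", "rectum"):
        assert quad.exceedance[name] == pytest.approx(mc.exceedance[name], abs=0.02)
        assert quad.p_mean[name] == pytest.approx(mc.p_mean[name], abs=0.02)


def test_posterior_input_validation():
    with pytest.raises(ValueError):
        posterior((CohortData(1, 4),), (0.03,))
    with pytest.raises(ValueError):
        posterior(TRIAL_DATA, NULLS, method="laplace")
    with pytest.raises(ValueError):
        HierarchicalPrior(mu_sd=0.0)
    with pytest.raises(ValueError):
        CohortData(5, 4)


def test_simulate_trial_degenerate_rates(published_design, shared_cache):
    design = published_design.with_gamma({"colon": 0.5, "rectum": 0.5})
    dead = simulate_trial(design, (0.0, 0.0), default_rng(1), shared_cache)
    assert dead.success == {"colon": False, "rectum": False}
    assert not dead.go
    sure = simulate_trial(design, (1.0, 1.0), default_rng(2), shared_cache)
    assert sure.go
    assert sure.final["colon"].x == sure.final["colon"].n == 28
    assert sure.final["rectum"].x == sure.final["rectum"].n == 16


def test_simulate_requires_calibration(published_design):
    with pytest.raises(ValueError):
        simulate_trial(published_design, (0.1, 0.1), default_rng(0))


def test_calibration_controls_null_and_is_seed_stable(published_design, shared_cache):
    cal_a = calibrate_gamma(published_design, n_sim=50_000, seed=11, cache=shared_cache)
    cal_b = calibrate_gamma(published_design, n_sim=50_000, seed=29, cache=shared_cache)
    for name in published_design.names:
        assert cal_a.null_success_rate[name] <= published_design.alpha
        assert abs(cal_a.gamma[name] - cal_b.gamma[name]) <= 0.02


def test_forcing_strictest_gamma_never_increases_null_success(published_design, shared_cache):
    cal = calibrate_gamma(published_design, n_sim=20_000, seed=3, cache=shared_cache)
    calibrated = published_design.with_gamma(cal.gamma)
    strict = published_design.with_gamma({n: 0.99 for n in published_design.names})
    oc_cal = operating_characteristics(calibrated, published_design.p_null,
                                       n_sim=20_000, seed=7, cache=shared_cache)
    oc_strict = operating_characteristics(strict, published_design.p_null,
                                          n_sim=20_000, seed=7, cache=shared_cache)
    for name in published_design.names:
        assert oc_strict.success[name] <= oc_cal.success[name]


def test_operating_characteristics_deterministic_given_seed(published_design, shared_cache):
    design = published_design.with_gamma({"colon": 0.5, "rectum": 0.5})
    a = operating_characteristics(design, (0.15, 0.35), n_sim=2_000, seed=5, cache=shared_cache)
    b = operating_characteristics(design, (0.15, 0.35), n_sim=2_000, seed=5, cache=shared_cache)
    assert a == b


def test_literal_rule_caps_colon_continuation(published_design, shared_cache):
    """Under the design alternative the printed joint rule terminates early
    most of the time: P(X >= 3 | 11, 0.15) = 0.221, so 80% power is out of
    reach for the literal reconstruction."""
    assert float(binom.sf(2, 11, 0.15)) == pytest.approx(0.2212, abs=2e-4)
    design = published_design.with_gamma({"colon": 0.5, "rectum": 0.5})
    oc = operating_characteristics(design, (0.15, 0.35), n_sim=4_000, seed=17, cache=shared_cache)
    pet = oc.early_termination["colon"]
    expected_go = float(binom.sf(2, 11, 0.15) * binom.sf(3, 8, 0.35))
    assert 1 - pet == pytest.approx(expected_go, abs=0.03)
    assert oc.success["colon"] < 0.5


def test_per_cohort_continuation_switch(published_design, shared_cache):
    import dataclasses

    solo = dataclasses.replace(published_design, continuation="per_cohort").with_gamma(
        {"colon": 0.5, "rectum": 0.5}
    )
    cache = ExceedanceCache(solo)
    oc = operating_characteristics(solo, (0.15, 0.35), n_sim=4_000, seed=17, cache=cache)
    # each cohort now continues on its own bar, so the colon success rate
    # is bounded by its own continuation probability, not the joint one
    assert 1 - oc.early_termination["colon"] == pytest.approx(
        float(binom.sf(2, 11, 0.15)), abs=0.03
    )


def test_pos_monotone_in_observed_responders(published_design, shared_cache):
    design = published_design.with_gamma({"colon": 0.5, "rectum": 0.5})
    values = [
        probability_of_success(
            design, (CohortData(x, 14), CohortData(6, 8)),
            n_sim=2_000, seed=13, cache=shared_cache,
        ).joint
        for x in (2, 8, 14)
    ]
    assert all(b >= a - 0.02 for a, b in zip(values, values[1:]))


def test_pos_low_when_data_sit_below_nulls(published_design, shared_cache):
    design = published_design.with_gamma({"colon": 0.5, "rectum": 0.5})
    res = probability_of_success(
        design, (CohortData(0, 14), CohortData(0, 8)), n_sim=2_000, seed=4,
        cache=shared_cache,
    )
    assert res.joint < 0.5


def test_pos_overenrolment_warns(published_design, shared_cache):
    design = published_design.with_gamma({"colon": 0.5, "rectum": 0.5})
    with pytest.warns(RuntimeWarning):
        res = probability_of_success(
            design, (CohortData(20, 30), CohortData(6, 8)), n_sim=500, seed=4,
            cache=shared_cache,
        )
    assert 0.0 <= res.joint <= 1.0
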