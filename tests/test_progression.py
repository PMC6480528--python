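"""Progression law: trajectories, threshold crossing, staging, mortality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adpkdsim import (
    MortalityParams,
    ProgressionParams,
    TreatmentEffect,
    TreatmentPolicy,
    baseline_growth_rate,
    build_profile,
    ckd_stage,
    egfr_at,
    egfr_decline_rate,
    simulate_patient,
    survival_probability,
    time_to_threshold,
    tkv_at,
)
from adpkdsim.cohorts import PatientBaseline, expectation_strata
from adpkdsim.progression import (
    piecewise_egfr,
    piecewise_time_to_threshold,
    sample_death_age,
    survival_integral,
)

PARAMS = ProgressionParams(kappa=3.873, gamma=0.30)


def _patient(age=38.7, egfr=81.61, tkv=1692.3, height=1.70, sex="female"):
    return PatientBaseline(id=0, age0=age, sex=sex, height=height, tkv0=tkv, egfr0=egfr)


def test_baseline_growth_rate_worked_examples():
    assert baseline_growth_rate(38.7, 1692.3, 1.70, PARAMS) == pytest.approx(
        0.0489038833, abs=1e-9
    )
    assert baseline_growth_rate(42.0, 2323.18, 1.70, PARAMS) == pytest.approx(
        0.0526054445, abs=1e-9
    )
    with pytest.raises(ValueError):
        baseline_growth_rate(40.0, 150.0 * 1.70, 1.70, PARAMS)  # zero growth
    with pytest.raises(ValueError):
        baseline_growth_rate(0.0, 1700.0, 1.70, PARAMS)


def test_tkv_exponential_growth():
    assert tkv_at(1692.3, 0.04891, 0.0) == 1692.3
    assert tkv_at(1692.3, 0.04891, 3.0) == pytest.approx(1959.9, abs=0.3)  # +15.8%
    assert tkv_at(1000.0, 0.0, 10.0) == 1000.0
    with pytest.raises(ValueError):
        tkv_at(1000.0, 0.05, -1.0)


def test_egfr_decline_rate_normalisation_and_monotonicity():
    assert egfr_decline_rate(1000.0, PARAMS) == pytest.approx(3.873)
    assert egfr_decline_rate(1692.3, PARAMS) == pytest.approx(4.53514, abs=1e-4)
    assert egfr_decline_rate(2026.3, PARAMS) == pytest.approx(4.78695, abs=1e-4)
    assert egfr_decline_rate(2500.0, PARAMS) > egfr_decline_rate(1500.0, PARAMS)
    with pytest.raises(ValueError):
        egfr_decline_rate(0.0, PARAMS)


def test_egfr_at_identity_and_linear_limit():
    p = _patient()
    g = baseline_growth_rate(p.age0, p.tkv0, p.height, PARAMS)
    assert egfr_at(p, g, PARAMS, 1.0, 0.0) == 81.61
    # gamma = 0 reduces to constant-slope decline
    linear = ProgressionParams(kappa=5.0, gamma=0.0)
    assert egfr_at(_patient(egfr=80.0), g, linear, 1.0, 2.0) == pytest.approx(70.0)
    with pytest.raises(ValueError):
        egfr_at(p, g, PARAMS, 1.5, 1.0)


@pytest.mark.parametrize("profile", ["overall", "ckd1", "ckd2", "ckd3", "reprise"])
@pytest.mark.parametrize("multiplier", [1.0, 0.684])
def test_time_to_threshold_inverts_egfr_at(fitted, profile, multiplier):
    params = fitted.progression()
    for _, p in expectation_strata(build_profile(profile)):
        g = baseline_growth_rate(p.age0, p.tkv0, p.height, params)
        T = time_to_threshold(p, g, params, multiplier)
        assert egfr_at(p, g, params, multiplier, T) == pytest.approx(
            params.esrd_threshold, abs=1e-9
        )


def test_time_to_threshold_monotonicities(fitted):
    params = fitted.progression()
    p = _patient()
    g = baseline_growth_rate(p.age0, p.tkv0, p.height, params)
    assert time_to_threshold(p, g, params, 0.684) > time_to_threshold(p, g, params, 1.0)
    bigger_kidney = _patient(tkv=2300.0)
    g2 = baseline_growth_rate(38.7, 2300.0, 1.70, params)
    assert time_to_threshold(bigger_kidney, g2, params) < time_to_threshold(p, g, params)
    lower_egfr = _patient(egfr=60.0)
    assert time_to_threshold(lower_egfr, g, params) < time_to_threshold(p, g, params)
    with pytest.raises(ValueError):
        time_to_threshold(_patient(egfr=10.0), g, params)


@pytest.mark.parametrize(
    "profile", ["overall", "ckd1", "ckd2", "ckd3", "mayo_1c_1e", "tempo44", "reprise"]
)
def test_closed_form_matches_euler_integration(fitted, profile):
    """Monthly explicit-Euler integration of the decline ODE stays within
    0.1 mL/min/1.73m^2 of the closed form over 30 years."""
    params = fitted.progression()
    h = 1.0 / 12.0
    for _, p in expectation_strata(build_profile(profile)):
        g = baseline_growth_rate(p.age0, p.tkv0, p.height, params)
        e = p.egfr0
        worst = 0.0
        for k in range(int(30 / h)):
            t = k * h
            e = max(e - h * egfr_decline_rate(tkv_at(p.tkv0, g, t), params), 0.0)
            closed = egfr_at(p, g, params, 1.0, t + h)
            worst = max(worst, abs(e - closed))
        assert worst <= 0.1


def test_ckd_stage_bands():
    assert ckd_stage(95.0) == "CKD 1"
    assert ckd_stage(90.0) == "CKD 1"   # inclusive lower bound of higher stage
    assert ckd_stage(81.61) == "CKD 2"
    assert ckd_stage(45.0) == "CKD 3"
    assert ckd_stage(20.0) == "CKD 4"
    assert ckd_stage(14.999) == "ESRD"
    with pytest.raises(ValueError):
        ckd_stage(-1.0)


def test_survival_probability_worked_example():
    mort = MortalityParams(makeham=0.0)
    assert survival_probability(mort, 38.7, 38.7) == 1.0
    assert survival_probability(mort, 38.7, 52.0) == pytest.approx(0.97396020, abs=1e-7)
    with pytest.raises(ValueError):
        survival_probability(mort, 52.0, 38.7)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(20, 60),
    d1=st.floats(0.1, 20),
    d2=st.floats(0.1, 20),
    scale=st.floats(0.1, 3.0),
)
def test_survival_is_multiplicative_and_bounded(a, d1, d2, scale):
    mort = MortalityParams(scale_multiplier=scale)
    b, c = a + d1, a + d1 + d2
    s_ab, s_bc, s_ac = (
        survival_probability(mort, a, b),
        survival_probability(mort, b, c),
        survival_probability(mort, a, c),
    )
    assert 0.0 < s_ac <= 1.0
    assert s_ac == pytest.approx(s_ab * s_bc, rel=1e-12)


def test_sampled_death_agrees_with_analytic_weights(fitted):
    """Monte-Carlo death sampling reproduces the analytic survival weight and
    the expected alive-years used by expectation mode."""
    mort = fitted.mortality()
    rng = np.random.default_rng(11)
    age0, T = 38.7, 13.3
    draws = np.array([sample_death_age(mort, age0, rng) for _ in range(50_000)])
    frac_alive = np.mean(draws > age0 + T)
    assert frac_alive == pytest.approx(
        survival_probability(mort, age0, age0 + T), abs=0.005
    )
    alive_years = np.mean(np.minimum(draws - age0, T))
    assert alive_years == pytest.approx(survival_integral(mort, age0, 0.0, T), abs=0.05)


def test_simulate_patient_null_policy_equals_natural_history(fitted):
    params, mort = fitted.progression(), fitted.mortality()
    p = _patient()
    g = baseline_growth_rate(p.age0, p.tkv0, p.height, params)
    null_policy = TreatmentPolicy(effect=TreatmentEffect("ckd_epi", "overall", 0.0))
    natural = simulate_patient(p, params, mort, None)
    treated = simulate_patient(p, params, mort, null_policy)
    assert natural.esrd_time == pytest.approx(treated.esrd_time, abs=1e-12)
    assert natural.esrd_time == pytest.approx(time_to_threshold(p, g, params), abs=1e-9)
    np.testing.assert_allclose(natural.egfr_series, treated.egfr_series)


def test_simulate_patient_treatment_slows_decline(fitted):
    params, mort = fitted.progression(), fitted.mortality()
    p = _patient()
    policy = TreatmentPolicy(effect=TreatmentEffect("reciprocal_creatinine", "overall", 0.316))
    nat = simulate_patient(p, params, mort, None)
    tr = simulate_patient(p, params, mort, policy)
    assert tr.esrd_time > nat.esrd_time
    assert tr.esrd_time == pytest.approx(nat.esrd_time + 5.1, abs=0.25)
    assert np.all(np.diff(tr.tkv_series) > 0)
    assert np.all(np.diff(nat.egfr_series) <= 0)
    # expectation mode: expected alive-years on treatment < calendar ESRD time
    assert 0 < tr.years_on_treatment < tr.esrd_time


def test_simulate_patient_stochastic_mode_is_seeded(fitted):
    params, mort = fitted.progression(), fitted.mortality()
    p = _patient()
    policy = TreatmentPolicy(
        effect=TreatmentEffect("reciprocal_creatinine", "overall", 0.316),
    )
    a = simulate_patient(p, params, mort, policy, mode="stochastic",
                         rng=np.random.default_rng(5))
    b = simulate_patient(p, params, mort, policy, mode="stochastic",
                         rng=np.random.default_rng(5))
    assert a.esrd_time == b.esrd_time
    assert a.death_time == b.death_time
    np.testing.assert_array_equal(a.egfr_series, b.egfr_series)
    with pytest.raises(ValueError):
        simulate_patient(p, params, mort, policy, mode="stochastic")  # rng required
    with pytest.raises(ValueError):
        simulate_patient(p, params, mort, None, horizon_age=30.0)


def test_piecewise_consistency_with_constant_multiplier(fitted):
    params = fitted.progression()
    p = _patient()
    g = baseline_growth_rate(p.age0, p.tkv0, p.height, params)
    segs = [(0.0, 40.0, 0.684)]
    assert piecewise_egfr(p, g, params, segs, 7.0) == pytest.approx(
        egfr_at(p, g, params, 0.684, 7.0), abs=1e-12
    )
    assert piecewise_time_to_threshold(p, g, params, segs) == pytest.approx(
        time_to_threshold(p, g, params, 0.684), abs=1e-10
    )
    # splitting an interval does not change anything
    split = [(0.0, 5.0, 0.684), (5.0, 40.0, 0.684)]
    assert piecewise_time_to_threshold(p, g, params, split) == pytest.approx(
        piecewise_time_to_threshold(p, g, params, segs), abs=1e-10
    )
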