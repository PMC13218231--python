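"""Cost and QALY accrual, savings arithmetic, and the NMB identity."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import ckdsim as ck
from ckdsim.economics import (
    CostRange,
    PatientYearRecord,
    accrue_annual_cost,
    accrue_qalys,
    compare_scenarios,
    compute_savings,
    net_monetary_benefit,
)
from ckdsim.errors import ContractViolationError
from ckdsim.states import HealthState


def test_cost_range_midpoint_and_bounds():
    r = CostRange(low=1_242, high=2_098)
    assert r.point == pytest.approx(1_670)
    with pytest.raises(ValidationError, match="outside its printed range"):
        CostRange(low=100, high=200, point=500)


def _schedule(bundle, **updates) -> ck.CostSchedule:
    return bundle.costs.model_copy(update=updates)


def test_treated_stage3a_year_cost(bundle):
    """A treated G3a patient-year with no events costs the stage point cost
    plus the SGLT2i acquisition cost."""
    stage = dict(bundle.costs.stage_costs)
    stage["g3a"] = CostRange(low=1_242, high=2_098, point=1_242)
    schedule = _schedule(bundle, stage_costs=stage)
    rec = PatientYearRecord(state=HealthState.G3aA2, age=76, on_sglt2i=True)
    assert accrue_annual_cost(rec, schedule) == pytest.approx(1_242 + 567)


def test_dead_patient_year_costs_nothing(bundle):
    rec = PatientYearRecord(state=HealthState.DEAD, age=80)
    assert accrue_annual_cost(rec, bundle.costs) == 0.0
    assert accrue_qalys(rec, bundle.utilities) == 0.0


def test_hemodialysis_year_cost(bundle):
    rec = PatientYearRecord(state=HealthState.HEMODIALYSIS, age=70)
    assert accrue_annual_cost(rec, bundle.costs) == pytest.approx(63_455 + 13)


def test_cvd_event_timing_acute_then_followup(bundle):
    """An acute cost lands in the event year; follow-up costs recur in every
    later alive year."""
    sched = bundle.costs
    event_year = PatientYearRecord(state=HealthState.G4A2, age=76,
                                   events={"mace": 1})
    later_year = PatientYearRecord(state=HealthState.G4A2, age=77,
                                   prior_cvd_events=frozenset({"mace"}))
    base = PatientYearRecord(state=HealthState.G4A2, age=76)
    base_cost = accrue_annual_cost(base, sched)
    assert accrue_annual_cost(event_year, sched) == pytest.approx(
        base_cost + sched.cvd_event_costs["mace"].acute
    )
    assert accrue_annual_cost(later_year, sched) == pytest.approx(
        base_cost + sched.cvd_event_costs["mace"].followup_annual
    )


def test_other_event_timing_rules(bundle):
    sched = bundle.costs
    base = accrue_annual_cost(PatientYearRecord(state=HealthState.G4A2, age=76), sched)
    per_event = PatientYearRecord(state=HealthState.G4A2, age=76, events={"aki": 2})
    assert accrue_annual_cost(per_event, sched) == pytest.approx(
        base + 2 * sched.other_event_costs["aki"].amount
    )
    first_year = PatientYearRecord(state=HealthState.G4A2, age=76,
                                   events={"new_diabetes": 1},
                                   first_occurrences=frozenset({"new_diabetes"}))
    assert accrue_annual_cost(first_year, sched) == pytest.approx(
        base + sched.other_event_costs["new_diabetes"].amount
    )
    chronic = PatientYearRecord(state=HealthState.G4A2, age=76,
                                chronic_cost_flags=frozenset({"anemia"}))
    assert accrue_annual_cost(chronic, sched) == pytest.approx(
        base + sched.other_event_costs["anemia"].amount
    )


def test_qaly_multiplication_and_disutility(bundle):
    """utility 0.8 x age factor 0.9 = 0.72; a one-time disutility applies in
    the event year only."""
    utils = bundle.utilities.model_copy(
        update={"g_utilities": [0.8] * 6, "age_grid": [18, 110],
                "age_utility": [0.9, 0.9],
                "event_disutilities": {"mace": 0.05}}
    )
    quiet = PatientYearRecord(state=HealthState.G3aA2, age=76)
    event = PatientYearRecord(state=HealthState.G3aA2, age=76, events={"mace": 1})
    assert accrue_qalys(quiet, utils) == pytest.approx(0.72)
    assert accrue_qalys(event, utils) == pytest.approx(0.67)
    # the year after the event is back at the state utility
    assert accrue_qalys(quiet, utils) == pytest.approx(0.72)


def test_age_adjusted_utility_never_exceeds_age_norm(bundle, rng):
    ages = rng.uniform(18, 110, 200)
    states = rng.integers(6, 18, 200)
    u = bundle.utilities.state_utility_vector(states) * bundle.utilities.age_adjustment(ages)
    assert (u <= bundle.utilities.age_adjustment(ages) + 1e-12).all()


def test_nmb_identity_machine_precision(rng):
    for _ in range(200):
        dq = rng.normal(0, 1e4)
        dc = rng.normal(0, 1e8)
        lam = rng.uniform(0, 1e5)
        assert net_monetary_benefit(dq, dc, lam) == lam * dq - dc
    assert net_monetary_benefit(123.0, 456.0, 0.0) == -456.0


def test_compute_savings_published_examples():
    """KRT 493.7 vs 261.1 -> 232.6 MEUR; totals 7,815.2 vs 7,528.3 -> 286.9."""
    savings = compute_savings(
        {"krt": 493.7, "total": 7_815.2}, {"krt": 261.1, "total": 7_528.3}
    )
    assert savings["krt"] == pytest.approx(232.6)
    assert savings["total"] == pytest.approx(286.9)
    zero = compute_savings({"krt": 1.0}, {"krt": 1.0})
    assert zero["krt"] == 0.0
    with pytest.raises(ContractViolationError):
        compute_savings({"krt": 1.0}, {"cvd": 1.0})


def _outcome_frame(rng, n=10):
    return pd.DataFrame({
        "year": np.arange(1, n + 1),
        "qalys": rng.uniform(1e3, 1e4, n),
        "cost_total": rng.uniform(1e6, 1e7, n),
        "cost_krt": rng.uniform(1e5, 1e6, n),
        "cost_cvd": rng.uniform(1e5, 1e6, n),
        "cost_stage": rng.uniform(1e5, 1e6, n),
        "cost_drug": rng.uniform(1e4, 1e5, n),
        "cost_other": rng.uniform(1e4, 1e5, n),
    })


def test_compare_scenario_with_itself_is_zero(rng):
    f = _outcome_frame(rng)
    cmp = compare_scenarios(f, f)
    assert cmp.delta_qaly == 0 and cmp.delta_cost == 0 and cmp.nmb == 0
    assert all(v == 0 for v in cmp.savings_by_category.values())


def test_compare_scenarios_nmb_identity_and_horizon_check(rng):
    a, b = _outcome_frame(rng), _outcome_frame(rng)
    cmp = compare_scenarios(a, b, lam=24_178.0)
    assert cmp.nmb == 24_178.0 * cmp.delta_qaly - cmp.delta_cost
    with pytest.raises(ContractViolationError):
        compare_scenarios(a, b.iloc[:-1])


def test_no_discounting_year_permutation_invariance(rng):
    """Permuting the year order of identical annual amounts changes nothing:
    totals are undiscounted sums."""
    a, b = _outcome_frame(rng), _outcome_frame(rng)
    perm = rng.permutation(len(a))
    cmp1 = compare_scenarios(a, b)
    cmp2 = compare_scenarios(a.iloc[perm].reset_index(drop=True),
                             b.iloc[perm].reset_index(drop=True))
    assert cmp1.nmb == pytest.approx(cmp2.nmb)
    assert cmp1.delta_qaly == pytest.approx(cmp2.delta_qaly)


def test_price_sensitivity_lowers_cost_leaves_events(bundle):
    """price_multiplier 0.2 strictly lowers treated-scenario costs while all
    event counts are unchanged under common random numbers."""
    pop = ck.build_population(bundle.prevalent_cohort, None, 1_000, 0, 5, seed=21,
                              slope_sd=bundle.progression.slope_sd)
    full = ck.simulate_arm(pop, bundle, treated=True, horizon=5, seed=21)
    cheap = ck.simulate_arm(pop, bundle, treated=True, horizon=5, seed=21,
                            price_multiplier=0.2)
    for col in ("deaths", "kf", "mace", "new_hf", "cvd_hosp", "krt_init_total"):
        assert full.outcomes[col].tolist() == cheap.outcomes[col].tolist()
    assert (cheap.outcomes["cost_total"] < full.outcomes["cost_total"]).all()


def test_costs_and_qalys_additive_over_patients(bundle):
    """Split-merge: simulating two half-populations separately sums to the
    whole within nothing but float addition order (same draws per slot are
    not guaranteed, so totals are compared via category sums instead)."""
    out = ck.simulate_arm(
        ck.build_population(bundle.prevalent_cohort, None, 800, 0, 4, seed=33,
                            slope_sd=bundle.progression.slope_sd),
        bundle, treated=False, horizon=4, seed=33,
    ).outcomes
    total = out["cost_total"]
    parts = out[["cost_stage", "cost_drug", "cost_krt", "cost_cvd", "cost_other"]].sum(axis=1)
    np.testing.assert_allclose(total, parts)
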