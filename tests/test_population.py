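"""Population dynamics: eligibility arithmetic, conservation, weighting."""

import numpy as np
import pandas as pd
import pytest

import ckdsim as ck
from ckdsim.errors import ContractViolationError, DomainError


@pytest.mark.parametrize(
    ("total", "frac", "expected"),
    [
        (251_946, 0.2675, 67_395),   # published national eligible pool
        (27_816, 0.2675, 7_440),     # published annual incident eligible
        (0, 0.5, 0),
    ],
)
def test_compute_eligible_floor_rule(total, frac, expected):
    assert ck.compute_eligible(total, frac) == expected


def test_eligible_breakdown_matches_published_split():
    cfg = ck.ScenarioConfig()
    total, prevalent, incident = ck.eligible_breakdown(cfg)
    assert (total, prevalent, incident) == (67_395, 59_955, 7_440)


@pytest.mark.parametrize(
    ("initial", "final", "expected"),
    [(251_946, 328_414, 30), (67_395, 87_256, 29)],
)
def test_growth_percentages(initial, final, expected):
    assert ck.growth_percentage(initial, final) == expected


def _toy_arms(n_years=5, seed=0):
    rng = np.random.default_rng(seed)
    years = np.arange(1, n_years + 1)
    t = pd.DataFrame({"year": years, "deaths": rng.integers(0, 50, n_years),
                      "cost_total": rng.uniform(0, 1e6, n_years),
                      "qalys": rng.uniform(0, 1e4, n_years)})
    u = pd.DataFrame({"year": years, "deaths": rng.integers(0, 50, n_years),
                      "cost_total": rng.uniform(0, 1e6, n_years),
                      "qalys": rng.uniform(0, 1e4, n_years)})
    return t, u


def test_weight_by_uptake_endpoints_and_midpoint():
    t, u = _toy_arms()
    pd.testing.assert_frame_equal(ck.weight_by_uptake(t, u, 0.0), u.astype(float),
                                  check_dtype=False)
    pd.testing.assert_frame_equal(ck.weight_by_uptake(t, u, 1.0), t.astype(float),
                                  check_dtype=False)
    mid = ck.weight_by_uptake(t, u, 0.5)
    for col in ("deaths", "cost_total", "qalys"):
        np.testing.assert_allclose(mid[col], (t[col] + u[col]) / 2)


def test_weight_by_uptake_linear_and_bounded():
    t, u = _toy_arms(seed=3)
    for uptake in (0.15, 0.5, 0.9):
        w = ck.weight_by_uptake(t, u, uptake)
        for col in ("deaths", "cost_total", "qalys"):
            lo = np.minimum(t[col], u[col])
            hi = np.maximum(t[col], u[col])
            assert ((w[col] >= lo - 1e-9) & (w[col] <= hi + 1e-9)).all()
    # linearity in uptake: w(u1) + w(u2) == 2 w((u1+u2)/2), cell by cell
    w1, w2 = ck.weight_by_uptake(t, u, 0.2), ck.weight_by_uptake(t, u, 0.8)
    wm = ck.weight_by_uptake(t, u, 0.5)
    for col in ("deaths", "cost_total", "qalys"):
        np.testing.assert_allclose(w1[col] + w2[col], 2 * wm[col])


def test_weight_by_uptake_rejects_mismatched_horizons():
    t, u = _toy_arms()
    with pytest.raises(ContractViolationError):
        ck.weight_by_uptake(t, u.iloc[:-1], 0.5)


def test_per_cycle_person_conservation(bundle):
    """alive_in + incident = alive_out + deaths, exactly, every cycle."""
    cfg = ck.ScenarioConfig(seed=2, microsim_scale=0.01)
    res = ck.run_scenario(cfg, bundle)
    for arm in (res.treated, res.untreated):
        o = arm.outcomes
        for t in range(len(o) - 1):
            alive_out = o["alive_start"][t] - o["deaths"][t]
            assert alive_out + o["incident_added"][t + 1] == o["alive_start"][t + 1]


def test_null_dynamics(null_hazard_bundle):
    """One year, no incidence, zero hazards: nobody dies, nothing happens."""
    frozen = null_hazard_bundle.progression.model_copy(update={"slope_sd": 0.0})
    b = null_hazard_bundle.model_copy(update={"progression": frozen})
    cfg = ck.ScenarioConfig(uptake=0.0, horizon_years=1, annual_incidence=0,
                            microsim_scale=0.01, seed=4)
    res = ck.run_scenario(cfg, b)
    row = res.outcomes_sim.iloc[0]
    assert row["deaths"] == 0
    for ev in ("mace", "new_hf", "cvd_hosp", "kf", "krt_init_total"):
        assert row[ev] == 0
    assert res.ledger.iloc[0]["alive_end"] == res.ledger.iloc[0]["eligible"]


def test_kf_monotone_in_uptake_under_crn(bundle):
    results = ck.run_uptake_scenarios(
        ck.ScenarioConfig(seed=5, microsim_scale=0.02), bundle, (0.0, 0.5, 1.0)
    )
    kf = {u: r.outcomes_sim["kf"].sum() for u, r in results.items()}
    assert kf[1.0] <= kf[0.5] <= kf[0.0]
    assert results[1.0].kf_risk <= results[0.0].kf_risk


def test_too_small_microsimulation_refused(bundle):
    with pytest.raises(DomainError, match="100 simulated persons"):
        ck.run_scenario(ck.ScenarioConfig(microsim_scale=1e-4), bundle)


def test_population_projection_zero_mortality(null_hazard_bundle):
    frozen = null_hazard_bundle.progression.model_copy(update={"slope_sd": 0.0})
    b = null_hazard_bundle.model_copy(update={"progression": frozen})
    cfg = ck.ScenarioConfig(uptake=0.0, microsim_scale=0.01, seed=6)
    res = ck.run_scenario(cfg, b)
    proj = ck.project_population_growth(cfg, res)
    expected_final = cfg.initial_total_ckd + 10 * cfg.annual_incidence
    assert proj["total_ckd"].iloc[-1] == pytest.approx(expected_final)


def test_population_projection_reports_growth(bundle):
    cfg = ck.ScenarioConfig(seed=1, microsim_scale=0.02)
    res = ck.run_scenario(cfg, bundle)
    proj = ck.project_population_growth(cfg, res)
    assert len(proj) == cfg.horizon_years + 1
    assert proj["calendar_year"].iloc[0] == 2026
    assert 20 <= proj.attrs["growth_pct"] <= 40
    assert proj["eligible"].iloc[0] == 67_395


def test_scenario_rerun_is_bit_identical(bundle):
    cfg = ck.ScenarioConfig(seed=9, microsim_scale=0.01)
    a = ck.run_scenario(cfg, bundle)
    b = ck.run_scenario(cfg, bundle)
    pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
    pd.testing.assert_frame_equal(a.ledger, b.ledger)
    c = ck.run_scenario(cfg.model_copy(update={"seed": 10}), bundle)
    assert not a.outcomes["deaths"].equals(c.outcomes["deaths"])


def test_outcomes_invariant_to_microsim_scale(bundle):
    """Doubling the simulated population changes the per-person outcome by
    less than 3 Monte-Carlo SDs."""
    small = ck.simulate_closed_cohort(bundle.prevalent_cohort, bundle, 2_000, 10,
                                      seed=12, uptake=0.15)
    large = ck.simulate_closed_cohort(bundle.prevalent_cohort, bundle, 4_000, 10,
                                      seed=12, uptake=0.15)
    p = large["kf_risk"]
    sd = np.sqrt(p * (1 - p) * (1 / 2_000 + 1 / 4_000))
    assert abs(small["kf_risk"] - large["kf_risk"]) <= 3 * sd
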