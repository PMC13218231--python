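"""Event engine: mortality surface, KRT machinery, complication draws,
and the mortality calibration, each checked against an independent oracle."""

import numpy as np
import pytest
from pydantic import ValidationError

import ckdsim as ck
from ckdsim.engine import simulate_closed_cohort
from ckdsim.errors import CalibrationError, ContractViolationError
from ckdsim.events import (
    EventRates,
    KrtTransitionMatrix,
    MortalitySurface,
    annual_death_probability,
    check_kidney_failure_threshold,
    krt_annual_transition,
    sample_events,
)
from ckdsim.states import HealthState


def _flat_surface(calibration=1.0):
    return MortalitySurface(
        age_grid=[40, 110],
        baseline_annual_hazard=[0.02, 0.02],
        relative_risk_grid=[[1.0] * 3] * 6,
        calibration_multiplier=calibration,
    )


def test_death_probability_identity_multiplier():
    """With RR = 1 and calibration 1, the probability is exactly the
    hazard-to-probability conversion of the age baseline."""
    p = annual_death_probability(70.0, HealthState.G3aA2, _flat_surface())
    assert p == pytest.approx(1 - np.exp(-0.02))


def test_death_probability_monotone_in_albuminuria(bundle):
    surface = bundle.mortality
    for g in range(6):
        ps = [annual_death_probability(76.0, HealthState(3 * g + a), surface)
              for a in range(3)]
        assert ps[0] <= ps[1] <= ps[2]


def test_death_probability_rejects_dead_and_krt(bundle):
    for state in (HealthState.DEAD, HealthState.HEMODIALYSIS):
        with pytest.raises(ContractViolationError):
            annual_death_probability(70.0, state, bundle.mortality)


def test_non_monotone_rr_grid_rejected():
    grid = [[1.0, 1.1, 1.2]] * 6
    grid[4] = [0.5, 1.1, 1.2]  # worse G with lower risk: invalid
    with pytest.raises(ValidationError, match="non-decreasing"):
        MortalitySurface(age_grid=[40, 110], baseline_annual_hazard=[0.02, 0.02],
                         relative_risk_grid=grid)


def test_krt_matrix_validated_at_load():
    with pytest.raises(ValidationError, match="row sum"):
        KrtTransitionMatrix(
            initiation_split={"hemodialysis": 0.5, "peritoneal_dialysis": 0.3,
                              "transplant": 0.2},
            transitions={"hemodialysis": {"dead": 0.9, "transplant": 0.2},
                         "peritoneal_dialysis": {}, "transplant": {}},
        )


def test_krt_identity_and_absorbing_rows(bundle, rng):
    identity = KrtTransitionMatrix(
        initiation_split=bundle.krt.initiation_split,
        transitions={"hemodialysis": {}, "peritoneal_dialysis": {}, "transplant": {}},
    )
    codes = np.array([18, 19, 20, 21] * 50)
    out = krt_annual_transition(codes, identity, rng.random(codes.size))
    assert (out == codes).all()

    lethal = KrtTransitionMatrix(
        initiation_split=bundle.krt.initiation_split,
        transitions={"hemodialysis": {"dead": 1.0}, "peritoneal_dialysis": {"dead": 1.0},
                     "transplant": {"dead": 1.0}},
    )
    out = krt_annual_transition(codes, lethal, rng.random(codes.size))
    assert (out == int(HealthState.DEAD)).all()


def test_krt_occupancy_matches_matrix_power_oracle(bundle):
    """Repeated one-year transitions reproduce the matrix-power distribution
    of the embedded 4-state Markov chain within 3 Monte-Carlo SDs."""
    krt = bundle.krt
    order = ["hemodialysis", "peritoneal_dialysis", "transplant"]
    P = np.zeros((4, 4))
    for i, row_key in enumerate(order):
        row = krt.transitions[row_key]
        for j, col_key in enumerate(order):
            P[i, j] = row.get(col_key, 0.0)
        P[i, 3] = row.get("dead", 0.0)
        P[i, i] = 1.0 - P[i].sum() + P[i, i]
    P[3, 3] = 1.0
    steps = 8
    expected = np.linalg.matrix_power(P, steps)[0]  # start in HD

    n = 4_000
    codes = np.full(n, int(HealthState.HEMODIALYSIS))
    rng = np.random.default_rng(5)
    for _ in range(steps):
        codes = krt_annual_transition(codes, krt, rng.random(n))
    for j, code in enumerate([18, 19, 20, 21]):
        observed = (codes == code).sum()
        sd = np.sqrt(n * expected[j] * (1 - expected[j]))
        assert abs(observed - n * expected[j]) <= 3 * sd + 1, code


def test_modality_split_multinomial_oracle(bundle):
    """Forcing a whole G5 cohort to initiate KRT reproduces the registry
    initiation split within 3 SD of the multinomial counts."""
    spec = bundle.prevalent_cohort.model_copy(
        update={"n_patients": 1_500,
                "stage_distribution": {"G3a": 0, "G3b": 0, "G4": 0, "G5": 1.0}}
    )
    surface = bundle.mortality.model_copy(update={"calibration_multiplier": 1e-12})
    krt = bundle.krt.model_copy(update={"initiation_probability": 1.0})
    b = bundle.model_copy(update={"mortality": surface, "krt": krt,
                                  "prevalent_cohort": spec})
    pop = ck.build_population(spec, None, 1_500, 0, 1, seed=13,
                              slope_sd=b.progression.slope_sd)
    res = ck.simulate_arm(pop, b, treated=False, horizon=1, seed=13)
    row = res.outcomes.iloc[0]
    inits = {"hemodialysis": row["hd_init"], "peritoneal_dialysis": row["pd_init"],
             "transplant": row["tx_init"]}
    total = sum(inits.values())
    assert total == 1_500  # everyone initiates
    for key, count in inits.items():
        p = bundle.krt.initiation_split[key]
        sd = np.sqrt(total * p * (1 - p))
        assert abs(count - total * p) <= 3 * sd, key


def test_kidney_failure_threshold_examples():
    assert not check_kidney_failure_threshold(20.0)
    assert check_kidney_failure_threshold(10.0)


def test_event_count_matches_poisson_binomial_oracle(bundle, rng):
    """The simulated MACE count over many patient-years equals the sum of the
    evaluated probabilities within 3 SD of the Poisson-binomial."""
    n = 20_000
    cov = dict(
        state_codes=rng.integers(6, 18, n), age=rng.uniform(60, 90, n),
        sbp=rng.uniform(110, 160, n), hba1c=rng.uniform(5, 8, n),
        has_diabetes=rng.random(n) < 0.2, has_cvd=rng.random(n) < 0.3,
        has_chf=rng.random(n) < 0.1, has_hypertension=rng.random(n) < 0.5,
    )
    p = bundle.events.probability("mace", **cov)
    assert ((p >= 0) & (p <= 1)).all()
    draws = sample_events(bundle.events, ["mace"],
                          {"mace": rng.random(n)}, **cov)
    count = draws["mace"].sum()
    sd = np.sqrt((p * (1 - p)).sum())
    assert abs(count - p.sum()) <= 3 * sd


def test_zero_rates_produce_no_events(null_hazard_bundle, rng):
    n = 500
    cov = dict(
        state_codes=np.full(n, 7), age=np.full(n, 76.0), sbp=np.full(n, 132.0),
        hba1c=np.full(n, 5.9), has_diabetes=np.zeros(n, bool),
        has_cvd=np.zeros(n, bool), has_chf=np.zeros(n, bool),
        has_hypertension=np.zeros(n, bool),
    )
    draws = sample_events(null_hazard_bundle.events, ["mace", "new_hf"],
                          {"mace": rng.random(n), "new_hf": rng.random(n)}, **cov)
    assert not draws["mace"].any() and not draws["new_hf"].any()


def test_new_onset_hf_is_incident_only(bundle):
    """A patient with existing heart failure can never have new-onset HF."""
    spec = bundle.prevalent_cohort.model_copy(
        update={"n_patients": 1_000,
                "comorbidity_prevalence": {"diabetes": 0.2, "cvd": 0.25,
                                           "hypertension": 0.5, "chf": 1.0}}
    )
    pop = ck.build_population(spec, None, 1_000, 0, 5, seed=3,
                              slope_sd=bundle.progression.slope_sd)
    res = ck.simulate_arm(pop, bundle, treated=False, horizon=5, seed=3)
    assert res.outcomes["new_hf"].sum() == 0


def test_cohort_mortality_matches_life_table_oracle(bundle, frozen_progression):
    """With progression frozen, each patient's death hazard depends only on
    the (fixed) state and advancing age, so cumulative mortality has the
    deterministic life-table form 1 - prod_t (1 - p_t); the microsimulation
    agrees within 3 SD."""
    spec = bundle.prevalent_cohort.model_copy(
        update={"stage_distribution": {"G3a": 0.7, "G3b": 0.25, "G4": 0.05, "G5": 0}}
    )
    frozen = frozen_progression.model_copy(update={"baseline_egfr_slope": -1e-9})
    b = bundle.model_copy(update={"progression": frozen, "prevalent_cohort": spec})
    n, horizon, seed = 4_000, 10, 23
    pop = ck.build_population(spec, None, n, 0, horizon, seed, slope_sd=0.0)
    res = ck.simulate_arm(pop, b, treated=False, horizon=horizon, seed=seed)

    surv = np.ones(n)
    for t in range(1, horizon + 1):
        p = ck.annual_death_probability(pop.age + t, pop.state, b.mortality)
        surv *= 1.0 - p
    q = 1.0 - surv
    expected = q.mean()
    sd = np.sqrt((q * (1 - q)).sum()) / n
    assert abs(res.died.mean() - expected) <= 3 * sd


def test_calibrate_mortality_fixed_point(bundle):
    """Targeting the mortality already produced by multiplier 1 recovers a
    multiplier close to 1."""
    base = bundle.mortality.model_copy(update={"calibration_multiplier": 1.0})
    b = bundle.model_copy(update={"mortality": base})
    target = simulate_closed_cohort(b.prevalent_cohort, b, 4_000, 10, seed=6)["mortality"]
    result = ck.calibrate_mortality(target, b, n_patients=4_000, seed=6)
    assert abs(result.multiplier - 1.0) < 0.25
    assert abs(result.achieved - target) <= 0.005 + 2 / 4_000


def test_calibrate_mortality_unreachable_target_reports_bracket(bundle):
    with pytest.raises(CalibrationError, match="not bracketed"):
        ck.calibrate_mortality(0.99, bundle, n_patients=500, seed=1,
                               bounds=(0.05, 0.1))
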