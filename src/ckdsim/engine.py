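"""Vectorised patient-level microsimulation engine.

One arm of a scenario (everyone treated, or no one treated) is simulated on
a fixed population with annual cycles.  Within a cycle the order of
operations is fixed and documented:

1. incident patients enter (treated arm: eligible entrants initiate, with
   the one-time acute eGFR dip),
2. treated patients may discontinue (reversible effect components removed),
3. disease progression: ages, marker drifts, covariate-adjusted eGFR slope,
   UACR growth, state reclassification,
4. death (evaluated first among events; a patient who dies this cycle
   accrues no further events, costs or QALYs for the cycle),
5. kidney failure (first entry into G5 among survivors) and KRT initiation
   / modality transitions,
6. cardiovascular and other complications among survivors,
7. cost and QALY accrual for patient-years alive at cycle end.

Randomness: every hazard type in every year draws one uniform per patient
slot from a named stream keyed by (scenario seed, hazard code, year).
Because patient slots are identical across arms, the two arms of a scenario
(and all uptake scenarios built from them) share common random numbers,
which makes uptake contrasts clean and monotone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .config import ParameterBundle
from .economics import CostSchedule, UtilitySchedule
from .events import EVENT_NAMES, KrtTransitionMatrix, krt_annual_transition
from .progression import ELIGIBLE_G_INDICES
from .states import HealthState, classify_codes

DEAD = int(HealthState.DEAD)
HD = int(HealthState.HEMODIALYSIS)
PD = int(HealthState.PERITONEAL_DIALYSIS)
TX = int(HealthState.TRANSPLANT)

# named hazard-stream codes (stable across versions; part of the CRN contract)
_STREAMS = {
    "discontinuation": 1,
    "death": 2,
    "krt_init": 3,
    "krt_modality": 4,
    "krt_transition": 5,
    "treatment_ae": 6,
    "mace": 10,
    "new_hf": 11,
    "cvd_hosp": 12,
    "aki": 13,
    "anemia": 14,
    "mbd": 15,
    "new_diabetes": 16,
    "new_hypertension": 17,
    "infection": 18,
    "other_ae": 19,
}
_SLOPE_RE_STREAM = 902
_COHORT_STREAM = 901

OUTCOME_COUNT_COLUMNS = [
    "alive_start", "incident_added", "deaths",
    "kf", "kf_or_krt", "hd_init", "pd_init", "tx_init", "krt_init_total",
    "mace", "new_hf", "cvd_hosp", "aki", "anemia", "mbd",
    "new_diabetes", "new_hypertension", "infection", "other_ae",
    "treatment_ae", "hd_prevalent", "pd_prevalent", "tx_prevalent",
]
OUTCOME_VALUE_COLUMNS = [
    "cost_stage", "cost_drug", "cost_krt", "cost_cvd", "cost_other",
    "cost_total", "qalys",
]


def _stream(seed: int, code: int, year: int) -> np.random.Generator:
    # derived entropy stays well below 2**31 per component
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), code, year]))


@dataclasses.dataclass
class Population:
    """Flat arrays for every patient that will ever enter the simulation."""

    entry_year: np.ndarray
    age: np.ndarray
    egfr: np.ndarray
    uacr: np.ndarray
    sbp: np.ndarray
    hba1c: np.ndarray
    has_diabetes: np.ndarray
    has_cvd: np.ndarray
    has_hypertension: np.ndarray
    has_chf: np.ndarray
    state: np.ndarray
    slope_re: np.ndarray

    @property
    def n(self) -> int:
        return self.age.size

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, slope_re: np.ndarray) -> "Population":
        return cls(
            entry_year=frame["entry_year"].to_numpy(np.int64),
            age=frame["age"].to_numpy(float),
            egfr=frame["egfr"].to_numpy(float),
            uacr=frame["uacr"].to_numpy(float),
            sbp=frame["sbp"].to_numpy(float),
            hba1c=frame["hba1c"].to_numpy(float),
            has_diabetes=frame["has_diabetes"].to_numpy(bool),
            has_cvd=frame["has_cvd"].to_numpy(bool),
            has_hypertension=frame["has_hypertension"].to_numpy(bool),
            has_chf=frame["has_chf"].to_numpy(bool),
            state=frame["state"].to_numpy(np.int64),
            slope_re=slope_re,
        )


def build_population(
    prevalent_spec: CohortSpec,
    incident_spec: CohortSpec | None,
    n_prevalent: int,
    n_incident_per_year: int,
    horizon: int,
    seed: int,
    slope_sd: float,
) -> Population:
    """Assemble prevalent + per-year incident cohorts with stable patient ids.

    Cohorts and slope random effects are keyed only by the scenario seed, so
    the identical population is used in every arm.
    """
    frames = []
    prev = generate_cohort(
        prevalent_spec.model_copy(update={"n_patients": n_prevalent}),
        seed=int(_stream(seed, _COHORT_STREAM, 0).integers(2**31)),
        entry_year=1,
    )
    frames.append(prev)
    offset = n_prevalent
    if incident_spec is not None and n_incident_per_year > 0:
        for t in range(1, horizon + 1):
            inc = generate_cohort(
                incident_spec.model_copy(update={"n_patients": n_incident_per_year}),
                seed=int(_stream(seed, _COHORT_STREAM, t).integers(2**31)),
                entry_year=t,
                id_offset=offset,
            )
            frames.append(inc)
            offset += n_incident_per_year
    frame = pd.concat(frames, ignore_index=True)
    slope_re = _stream(seed, _SLOPE_RE_STREAM, 0).normal(0.0, slope_sd, len(frame))
    return Population.from_frame(frame, slope_re)


@dataclasses.dataclass
class ArmResult:
    """Per-year outcomes of one arm, in *simulated* persons/EUR/QALYs."""

    outcomes: pd.DataFrame
    #: per-patient flags at end of horizon
    died: np.ndarray
    had_kf: np.ndarray
    n_patients: int

    def cumulative(self, column: str) -> float:
        return float(self.outcomes[column].sum())


def _event_covariates(bundle, state, age, eff_sbp, eff_hba1c, d, cvd, chf, htn, mask):
    return dict(
        state_codes=state[mask], age=age[mask], sbp=eff_sbp[mask], hba1c=eff_hba1c[mask],
        has_diabetes=d[mask], has_cvd=cvd[mask], has_chf=chf[mask], has_hypertension=htn[mask],
    )


def simulate_arm(
    pop: Population,
    bundle: ParameterBundle,
    *,
    treated: bool,
    horizon: int,
    seed: int,
    effect_scale: float | None = None,
    price_multiplier: float | None = None,
) -> ArmResult:
    """Simulate one arm over ``horizon`` annual cycles.

    ``effect_scale`` / ``price_multiplier`` override the bundle's values
    (sensitivity analyses); the underlying random streams depend only on
    ``seed``, the hazard type and the year.
    """
    params = bundle.progression
    effect = bundle.treatment
    if effect_scale is not None:
        effect = effect.model_copy(update={"effect_scale": effect_scale})
    costs: CostSchedule = bundle.costs
    if price_multiplier is not None:
        costs = costs.model_copy(update={"price_multiplier": price_multiplier})
    utils: UtilitySchedule = bundle.utilities
    krt: KrtTransitionMatrix = bundle.krt
    surface = bundle.mortality
    mods = params.slope_modifiers

    n = pop.n
    age = pop.age.copy()
    egfr = pop.egfr.copy()
    uacr = pop.uacr.copy()
    sbp = pop.sbp.copy()
    hba1c = pop.hba1c.copy()
    state = pop.state.copy()
    has_diabetes = pop.has_diabetes.copy()
    has_cvd = pop.has_cvd.copy()
    has_htn = pop.has_hypertension.copy()
    has_chf = pop.has_chf.copy()
    entry = pop.entry_year

    on_trt = np.zeros(n, dtype=bool)
    dip_applied = np.zeros(n, dtype=float)
    had_kf = np.zeros(n, dtype=bool)
    kf_krt_counted = np.zeros(n, dtype=bool)
    baseline_g5 = (state < 18) & (state // 3 == 5)
    # follow-up cost flags; baseline CVD history counts as a prior CVD event
    prior_mace = pop.has_cvd.copy()
    prior_hf = np.zeros(n, dtype=bool)
    prior_hosp = np.zeros(n, dtype=bool)
    ever_anemia = np.zeros(n, dtype=bool)
    ever_mbd = np.zeros(n, dtype=bool)

    m_eff = effect.scaled_slope_multiplier
    dip_eff = effect.scaled_dip
    uacr_f = effect.scaled_uacr_factor
    sbp_red = effect.scaled_sbp_reduction
    hba_red = effect.scaled_hba1c_reduction

    split_cum = krt.split_cumulative()
    disutil = utils.event_disutilities
    rows = []

    for t in range(1, horizon + 1):
        present = entry <= t
        alive = state != DEAD
        active = present & alive
        alive_start = int(active.sum())
        incident_added = int((entry == t).sum())
        row: dict[str, float] = {"year": t, "alive_start": alive_start,
                                 "incident_added": incident_added}

        # 1. treatment initiation for entrants (treated arm only)
        if treated:
            g = np.where(state < 18, state // 3, -1)
            entrants = (entry == t) & np.isin(g, ELIGIBLE_G_INDICES)
            on_trt |= entrants
            egfr[entrants] = np.maximum(egfr[entrants] - dip_eff, params.egfr_floor)
            dip_applied[entrants] = dip_eff

        # 2. discontinuation
        if treated and effect.annual_discontinuation_probability > 0:
            u = _stream(seed, _STREAMS["discontinuation"], t).random(n)
            disc = on_trt & active & (u < effect.annual_discontinuation_probability)
            egfr[disc] += dip_applied[disc]
            dip_applied[disc] = 0.0
            on_trt[disc] = False

        # 3. progression (grid states only); everyone alive ages
        grid = active & (state < 18)
        krt_now = active & (state >= HD) & (state < DEAD)
        age[active] += 1.0
        sbp[active] += params.sbp_annual_drift
        hba1c[active] += params.hba1c_annual_drift
        eff_sbp = sbp - sbp_red * on_trt
        eff_hba1c = hba1c - hba_red * on_trt
        eff_uacr = np.where(on_trt, uacr * uacr_f, uacr)

        a_idx = np.where(eff_uacr < 30.0, 0, np.where(eff_uacr <= 300.0, 1, 2))
        slope = (
            params.baseline_egfr_slope
            + mods.age_per_decade * (age - mods.ref_age) / 10.0
            + mods.diabetes * has_diabetes
            + mods.hypertension * has_htn
            + mods.sbp_per_10mmhg * (eff_sbp - mods.ref_sbp) / 10.0
            + mods.hba1c_per_unit * (eff_hba1c - mods.ref_hba1c)
            + mods.uacr_a2 * (a_idx == 1)
            + mods.uacr_a3 * (a_idx == 2)
            + pop.slope_re
        )
        slope = np.minimum(slope, 0.0)
        mult = np.where(on_trt, m_eff, 1.0)
        was_g5 = grid & (state // 3 == 5)
        egfr[grid] = np.maximum(egfr[grid] + (slope * mult)[grid], params.egfr_floor)
        uacr[grid] = np.minimum(uacr[grid] * (1.0 + params.uacr_annual_growth), params.uacr_cap)
        eff_uacr = np.where(on_trt, uacr * uacr_f, uacr)
        state[grid] = classify_codes(egfr[grid], eff_uacr[grid])
        entered_g5 = grid & ~was_g5 & (state // 3 == 5) & (state < 18)
        # trial effects were not applied to stage 5: treatment ceases at KF
        stop5 = on_trt & entered_g5
        on_trt[stop5] = False
        dip_applied[stop5] = 0.0

        # 4. death first among events
        u_death = _stream(seed, _STREAMS["death"], t).random(n)
        p_death = np.zeros(n)
        if grid.any():
            hz = surface.baseline(age[grid]) * surface.rr(state[grid])
            p_death[grid] = 1.0 - np.exp(-hz * surface.calibration_multiplier)
        die_grid = grid & (u_death < p_death)
        state[die_grid] = DEAD

        # KRT annual transitions (their rows include death)
        krt_deaths = 0
        hd_init = pd_init = tx_init = 0
        if krt_now.any():
            u_tr = _stream(seed, _STREAMS["krt_transition"], t).random(n)
            old = state[krt_now]
            new = krt_annual_transition(old, krt, u_tr[krt_now])
            krt_deaths = int((new == DEAD).sum())
            hd_init += int(((new == HD) & (old != HD)).sum())
            pd_init += int(((new == PD) & (old != PD)).sum())
            tx_init += int(((new == TX) & (old != TX)).sum())
            state[krt_now] = new

        deaths = int(die_grid.sum()) + krt_deaths
        row["deaths"] = deaths

        # 5. kidney failure and KRT initiation among survivors
        kf_new = entered_g5 & (state != DEAD) & ~had_kf
        had_kf |= kf_new
        row["kf"] = int(kf_new.sum())
        g5_alive = (state < 18) & (state // 3 == 5) & present
        u_init = _stream(seed, _STREAMS["krt_init"], t).random(n)
        initiate = g5_alive & (u_init < krt.initiation_probability)
        if initiate.any():
            u_mod = _stream(seed, _STREAMS["krt_modality"], t).random(n)
            midx = np.searchsorted(split_cum, u_mod[initiate], side="right")
            midx = np.minimum(midx, 2)
            new_states = np.array([HD, PD, TX])[midx]
            state[initiate] = new_states
            hd_init += int((new_states == HD).sum())
            pd_init += int((new_states == PD).sum())
            tx_init += int((new_states == TX).sum())
        # "KF or KRT" counts each patient once, at KF or (for patients already
        # in G5 at model entry) at first KRT initiation
        kf_krt_new = (kf_new | (initiate & baseline_g5)) & ~kf_krt_counted
        kf_krt_counted |= kf_krt_new
        row["kf_or_krt"] = int(kf_krt_new.sum())
        row["hd_init"], row["pd_init"], row["tx_init"] = hd_init, pd_init, tx_init
        row["krt_init_total"] = hd_init + pd_init + tx_init

        # 6. complications among survivors (death already evaluated)
        surv = present & (state != DEAD)
        cov = dict(
            state_codes=state[surv], age=age[surv], sbp=eff_sbp[surv],
            hba1c=eff_hba1c[surv], has_diabetes=has_diabetes[surv],
            has_cvd=has_cvd[surv], has_chf=has_chf[surv],
            has_hypertension=has_htn[surv],
        )
        event_occurrence: dict[str, np.ndarray] = {}
        for ev in EVENT_NAMES:
            u_ev = _stream(seed, _STREAMS[ev], t).random(n)
            p = np.zeros(n)
            p[surv] = bundle.events.probability(ev, **cov)
            occ = surv & (u_ev < p)
            if ev == "new_hf":
                occ &= ~has_chf
            elif ev == "new_diabetes":
                occ &= ~has_diabetes
            elif ev == "new_hypertension":
                occ &= ~has_htn
            event_occurrence[ev] = occ
            row[ev] = int(occ.sum())
        trt_ae = np.zeros(n, dtype=bool)
        if treated and effect.adverse_event_rates:
            u_ae = _stream(seed, _STREAMS["treatment_ae"], t).random(n)
            total_rate = sum(effect.adverse_event_rates.values())
            trt_ae = surv & on_trt & (u_ae < total_rate)
        row["treatment_ae"] = int(trt_ae.sum())

        # 7. economics for patient-years alive at cycle end
        alive_end = surv
        state_cost = costs.state_cost_vector(state) * alive_end
        is_krt_state = (state >= HD) & (state < DEAD)
        cost_krt = float(state_cost[is_krt_state & alive_end].sum())
        cost_stage = float(state_cost.sum()) - cost_krt
        drug = np.where(
            alive_end & on_trt,
            costs.sglt2i_annual * costs.price_multiplier,
            np.where(alive_end, costs.soc_annual, 0.0),
        )
        cost_drug = float(drug.sum())
        cvd_cost = (
            event_occurrence["mace"] * costs.cvd_event_costs["mace"].acute
            + event_occurrence["new_hf"] * costs.cvd_event_costs["new_hf"].acute
            + event_occurrence["cvd_hosp"] * costs.cvd_event_costs["cvd_hosp"].acute
            + (prior_mace & alive_end) * costs.cvd_event_costs["mace"].followup_annual
            + (prior_hf & alive_end) * costs.cvd_event_costs["new_hf"].followup_annual
            + (prior_hosp & alive_end) * costs.cvd_event_costs["cvd_hosp"].followup_annual
        )
        cost_cvd = float(cvd_cost.sum())
        oc = costs.other_event_costs
        other_cost = (
            event_occurrence["aki"] * oc["aki"].amount
            + event_occurrence["infection"] * oc["infection"].amount
            + event_occurrence["other_ae"] * oc["other_ae"].amount
            + event_occurrence["new_diabetes"] * oc["new_diabetes"].amount
            + event_occurrence["new_hypertension"] * oc["new_hypertension"].amount
            + ((ever_anemia | event_occurrence["anemia"]) & alive_end) * oc["anemia"].amount
            + ((ever_mbd | event_occurrence["mbd"]) & alive_end) * oc["mbd"].amount
            + trt_ae * oc["treatment_adverse_event"].amount
        )
        cost_other = float(other_cost.sum())
        row["cost_stage"] = cost_stage
        row["cost_drug"] = cost_drug
        row["cost_krt"] = cost_krt
        row["cost_cvd"] = cost_cvd
        row["cost_other"] = cost_other
        row["cost_total"] = cost_stage + cost_drug + cost_krt + cost_cvd + cost_other

        q = utils.state_utility_vector(state) * utils.age_adjustment(age)
        for ev in EVENT_NAMES:
            q -= disutil.get(ev, 0.0) * event_occurrence[ev]
        q -= disutil.get("treatment_adverse_event", 0.0) * trt_ae
        q = np.maximum(q, 0.0)
        row["qalys"] = float(q[alive_end].sum())

        # update history flags after costing (follow-up starts next year)
        prior_mace |= event_occurrence["mace"]
        prior_hf |= event_occurrence["new_hf"]
        prior_hosp |= event_occurrence["cvd_hosp"]
        ever_anemia |= event_occurrence["anemia"]
        ever_mbd |= event_occurrence["mbd"]
        has_chf |= event_occurrence["new_hf"]
        has_diabetes |= event_occurrence["new_diabetes"]
        has_htn |= event_occurrence["new_hypertension"]

        row["hd_prevalent"] = int((state[present] == HD).sum())
        row["pd_prevalent"] = int((state[present] == PD).sum())
        row["tx_prevalent"] = int((state[present] == TX).sum())
        rows.append(row)

    outcomes = pd.DataFrame(rows)
    return ArmResult(
        outcomes=outcomes,
        died=(state == DEAD) & (entry <= horizon),
        had_kf=had_kf,
        n_patients=n,
    )


def simulate_closed_cohort(
    cohort_spec: CohortSpec,
    bundle: ParameterBundle,
    n_patients: int,
    horizon: int,
    seed: int,
    uptake: float = 0.0,
    effect_scale: float | None = None,
) -> dict[str, float]:
    """Closed-cohort run (no incident inflow) returning uptake-weighted
    10-year cumulative kidney-failure risk and mortality.

    Both arms are simulated on the identical population with common random
    numbers and combined as ``uptake * treated + (1 - uptake) * untreated``.
    """
    pop = build_population(
        cohort_spec, None, n_patients, 0, horizon, seed, bundle.progression.slope_sd
    )
    untreated = simulate_arm(
        pop, bundle, treated=False, horizon=horizon, seed=seed, effect_scale=effect_scale
    )
    results = {"kf_risk_untreated": untreated.had_kf.mean(),
               "mortality_untreated": untreated.died.mean()}
    if uptake > 0:
        trt = simulate_arm(
            pop, bundle, treated=True, horizon=horizon, seed=seed, effect_scale=effect_scale
        )
        results["kf_risk_treated"] = trt.had_kf.mean()
        results["mortality_treated"] = trt.died.mean()
    else:
        results["kf_risk_treated"] = results["kf_risk_untreated"]
        results["mortality_treated"] = results["mortality_untreated"]
    results["kf_risk"] = (
        uptake * results["kf_risk_treated"] + (1 - uptake) * results["kf_risk_untreated"]
    )
    results["mortality"] = (
        uptake * results["mortality_treated"] + (1 - uptake) * results["mortality_untreated"]
    )
    return {k: float(v) for k, v in results.items()}
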