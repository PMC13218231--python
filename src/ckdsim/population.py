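"""Dynamic national-population engine.

The prevalent eligible pool plus one incident eligible cohort per year is
microsimulated at a configurable scale; deaths are removed before the
eligible count is recomputed each year.  Each uptake scenario combines a
fully treated and a fully untreated arm, simulated on the identical
population with common random numbers, by proportional weighting:

    outcome(uptake) = uptake * treated + (1 - uptake) * untreated

so the three base-case scenarios (15 %, 50 %, 90 %) differ only in a
scalar and scenario contrasts are monotone by construction.

Person-count conventions: eligibility uses floor rounding
(``floor(0.2675 * 251,946) = 67,395`` and ``floor(0.2675 * 27,816) =
7,440``); the prevalent eligible cohort is the difference of the two
(59,955).  Simulated counts are rescaled to represented persons only at
the reporting layer.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .config import ParameterBundle
from .economics import DEFAULT_LAMBDA
from .engine import ArmResult, Population, build_population, simulate_arm
from .errors import ContractViolationError, DomainError


class ScenarioConfig(BaseModel):
    """One uptake scenario plus the population and sensitivity switches."""

    uptake: float = Field(0.15, ge=0, le=1)
    start_year: int = 2026
    horizon_years: int = Field(10, ge=1)
    initial_total_ckd: int = Field(251_946, gt=0)
    #: zero is allowed to support closed-population analyses
    annual_incidence: int = Field(27_816, ge=0)
    eligibility_fraction: float = Field(0.2675, gt=0, le=1)
    #: simulated persons per represented person
    microsim_scale: float = Field(0.1668, gt=0)
    seed: int = 1
    lam: float = DEFAULT_LAMBDA
    # sensitivity switches
    effect_scale: float = Field(1.0, ge=0, le=1)
    price_multiplier: float = Field(1.0, gt=0)
    mortality_target: float | None = Field(None, gt=0, lt=1)
    # KRT capacity reporting
    krt_capacity_band: tuple[float, float] = (2500.0, 2700.0)
    current_krt_patients: float = 2600.0
    krt_baseline_eligible_share: float = Field(0.70, ge=0, le=1)


def compute_eligible(total_ckd: float, eligibility_fraction: float) -> int:
    """Eligible persons = floor(eligibility_fraction x CKD population)."""
    if total_ckd < 0 or eligibility_fraction < 0:
        raise DomainError("inputs must be non-negative")
    return math.floor(total_ckd * eligibility_fraction)


def eligible_breakdown(config: ScenarioConfig) -> tuple[int, int, int]:
    """(total eligible, prevalent eligible, incident eligible) at start."""
    total = compute_eligible(config.initial_total_ckd, config.eligibility_fraction)
    incident = compute_eligible(config.annual_incidence, config.eligibility_fraction)
    return total, total - incident, incident


def weight_by_uptake(
    treated_arm: pd.DataFrame, untreated_arm: pd.DataFrame, uptake: float
) -> pd.DataFrame:
    """Proportionally weight every additive outcome, year by year."""
    if len(treated_arm) != len(untreated_arm):
        raise ContractViolationError("arm horizons differ")
    if not 0 <= uptake <= 1:
        raise DomainError("uptake must lie in [0, 1]")
    out = treated_arm.copy()
    for col in treated_arm.columns:
        if col == "year":
            if not (treated_arm[col].to_numpy() == untreated_arm[col].to_numpy()).all():
                raise ContractViolationError("arm year indices differ")
            continue
        out[col] = uptake * treated_arm[col] + (1 - uptake) * untreated_arm[col]
    return out


@dataclasses.dataclass
class ScenarioResult:
    """Weighted per-year outcomes of one uptake scenario."""

    config: ScenarioConfig
    #: weighted per-year outcomes in simulated units
    outcomes_sim: pd.DataFrame
    #: weighted per-year outcomes rescaled to represented persons / EUR
    outcomes: pd.DataFrame
    ledger: pd.DataFrame
    treated: ArmResult
    untreated: ArmResult
    #: represented persons per simulated person
    representation_factor: float

    @property
    def kf_risk(self) -> float:
        """Uptake-weighted cumulative kidney-failure risk over the horizon."""
        u = self.config.uptake
        return float(
            u * self.treated.had_kf.mean() + (1 - u) * self.untreated.had_kf.mean()
        )

    @property
    def mortality(self) -> float:
        u = self.config.uptake
        return float(u * self.treated.died.mean() + (1 - u) * self.untreated.died.mean())


def _build_ledger(
    config: ScenarioConfig, weighted: pd.DataFrame, factor: float
) -> pd.DataFrame:
    """Per-year population ledger in represented persons.

    The conservation identity alive_out = alive_in + incident - deaths holds
    exactly in simulated counts; the represented columns are the same
    numbers rescaled.
    """
    rows = []
    treated_share = config.uptake
    for _, r in weighted.iterrows():
        alive_in = r["alive_start"]
        rows.append(
            {
                "year": int(r["year"]),
                "calendar_year": config.start_year + int(r["year"]) - 1,
                "eligible": alive_in * factor,
                "treated": treated_share * alive_in * factor,
                "incident_added": r["incident_added"] * factor,
                "deaths": r["deaths"] * factor,
                "alive_end": (alive_in - r["deaths"]) * factor,
            }
        )
    return pd.DataFrame(rows)


def run_scenario(
    config: ScenarioConfig,
    bundle: ParameterBundle,
    population: Population | None = None,
) -> ScenarioResult:
    """Simulate one uptake scenario (two arms + proportional weighting).

    A prebuilt :class:`~ckdsim.engine.Population` may be supplied so several
    uptake scenarios share the identical population and random streams.
    """
    _, prevalent_repr, incident_repr = eligible_breakdown(config)
    n_prev = int(round(config.microsim_scale * prevalent_repr))
    n_inc = int(round(config.microsim_scale * incident_repr))
    if n_prev + n_inc < 100:
        raise DomainError(
            "microsim_scale yields fewer than 100 simulated persons; "
            "Monte-Carlo error would dominate - increase microsim_scale"
        )
    if population is None:
        population = build_population(
            bundle.prevalent_cohort,
            bundle.incident_cohort,
            n_prev,
            n_inc,
            config.horizon_years,
            config.seed,
            bundle.progression.slope_sd,
        )
    common = dict(
        horizon=config.horizon_years,
        seed=config.seed,
        effect_scale=config.effect_scale,
        price_multiplier=config.price_multiplier,
    )
    treated = simulate_arm(population, bundle, treated=True, **common)
    untreated = simulate_arm(population, bundle, treated=False, **common)
    weighted = weight_by_uptake(treated.outcomes, untreated.outcomes, config.uptake)

    factor = 1.0 / config.microsim_scale
    outcomes = weighted.copy()
    for col in outcomes.columns:
        if col != "year":
            outcomes[col] = outcomes[col] * factor
    outcomes.insert(1, "calendar_year", config.start_year + outcomes["year"].astype(int) - 1)

    ledger = _build_ledger(config, weighted, factor)
    return ScenarioResult(
        config=config,
        outcomes_sim=weighted,
        outcomes=outcomes,
        ledger=ledger,
        treated=treated,
        untreated=untreated,
        representation_factor=factor,
    )


def run_uptake_scenarios(
    base_config: ScenarioConfig,
    bundle: ParameterBundle,
    uptakes: tuple[float, ...] = (0.15, 0.50, 0.90),
) -> dict[float, ScenarioResult]:
    """Run several uptake scenarios on shared arms and random numbers."""
    _, prevalent_repr, incident_repr = eligible_breakdown(base_config)
    n_prev = int(round(base_config.microsim_scale * prevalent_repr))
    n_inc = int(round(base_config.microsim_scale * incident_repr))
    population = build_population(
        bundle.prevalent_cohort,
        bundle.incident_cohort,
        n_prev,
        n_inc,
        base_config.horizon_years,
        base_config.seed,
        bundle.progression.slope_sd,
    )
    out = {}
    for u in uptakes:
        cfg = base_config.model_copy(update={"uptake": u})
        out[u] = run_scenario(cfg, bundle, population=population)
    return out


def project_population_growth(
    config: ScenarioConfig, scenario: ScenarioResult
) -> pd.DataFrame:
    """Total CKD G3-G5 population per calendar year under the scenario.

    The eligible microsimulation supplies the annual death *rate*; the whole
    CKD pool (eligible and non-eligible alike) is assumed subject to the
    same mortality surface, receives the configured incident inflow each
    year, and is never cured.  The final row reports the percentage growth
    over the horizon.
    """
    sim = scenario.outcomes_sim
    totals = [float(config.initial_total_ckd)]
    eligibles = [float(compute_eligible(config.initial_total_ckd, config.eligibility_fraction))]
    for _, r in sim.iterrows():
        rate = r["deaths"] / r["alive_start"] if r["alive_start"] > 0 else 0.0
        nxt = totals[-1] * (1.0 - rate) + config.annual_incidence
        totals.append(nxt)
        eligibles.append(float(compute_eligible(nxt, config.eligibility_fraction)))
    years = [config.start_year + k for k in range(len(totals))]
    frame = pd.DataFrame({"calendar_year": years, "total_ckd": totals,
                          "eligible": eligibles})
    frame.attrs["growth_pct"] = round((totals[-1] / totals[0] - 1.0) * 100.0)
    frame.attrs["eligible_growth_pct"] = round((eligibles[-1] / eligibles[0] - 1.0) * 100.0)
    return frame


def growth_percentage(initial: float, final: float) -> int:
    """Percentage growth rounded to the nearest integer."""
    if initial <= 0:
        raise DomainError("initial population must be positive")
    return round((final / initial - 1.0) * 100.0)
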