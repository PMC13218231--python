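"""Costs, utilities, QALYs, savings and net monetary benefit.

Costing rules
-------------
* Each alive patient-year accrues the annual cost of its health state
  (KDIGO stage cost, or the KRT modality cost; transplant additionally
  accrues immunosuppressive therapy) plus the drug cost: SGLT2i while
  treated and persisting, otherwise standard of care.
* CVD complications (MACE, new-onset heart failure, CVD hospitalisation)
  carry an acute cost in the year of the event and a follow-up cost in
  every subsequent year the patient remains alive.
* Other complications are costed per event, annually after first
  occurrence, or in the first year only, per the schedule's timing rule.
* Amounts are in EUR (fixed 7.46 DKK/EUR, price year 2024) and no
  discounting is applied: a euro in year 10 counts like a euro in year 1,
  as budget-impact guidance prescribes.
* ``price_multiplier`` applies to the SGLT2i acquisition cost only (0.2 in
  the 80 %-price-reduction sensitivity analysis).

QALYs are state utility x age-specific population utility, minus one-time
event disutilities in the cycle of occurrence, floored at zero; the dead
contribute nothing.  Net monetary benefit between two uptake scenarios is
``NMB = lambda * dQALY - dCost`` at willingness-to-pay lambda.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ContractViolationError, ScheduleLookupError
from .events import CVD_EVENT_NAMES
from .states import HealthState

#: willingness-to-pay threshold, EUR per QALY
DEFAULT_LAMBDA = 24_178.0

STAGE_COST_KEYS = ("g1", "g2", "g3a", "g3b", "g4", "g5")


class CostRange(BaseModel):
    """A cost given as a printed [low, high] range with a chosen point value.

    The point defaults to the midpoint; it must lie within the range.
    """

    low: float = Field(ge=0)
    high: float = Field(ge=0)
    point: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "CostRange":
        if self.high < self.low:
            raise ValueError("high < low")
        if self.point is None:
            self.point = (self.low + self.high) / 2.0
        if not self.low <= self.point <= self.high:
            raise ValueError("point cost outside its printed range")
        return self

    @classmethod
    def fixed(cls, value: float) -> "CostRange":
        return cls(low=value, high=value, point=value)


class CvdEventCost(BaseModel):
    acute: float = Field(ge=0)
    followup_annual: float = Field(ge=0)


class OtherEventCost(BaseModel):
    amount: float = Field(ge=0)
    timing: Literal["per_event", "annual", "first_year"]


class CostSchedule(BaseModel):
    """All unit costs of the model, EUR, price year 2024."""

    stage_costs: dict[str, CostRange]
    hemodialysis_annual: float = Field(63_455.0, ge=0)
    peritoneal_dialysis: CostRange = Field(
        default_factory=lambda: CostRange(low=36_869, high=42_572)
    )
    transplant: CostRange = Field(default_factory=lambda: CostRange(low=37_481, high=44_603))
    immunosuppression_annual: float = Field(10_678.0, ge=0)
    sglt2i_annual: float = Field(567.0, ge=0)
    soc_annual: float = Field(13.0, ge=0)
    cvd_event_costs: dict[str, CvdEventCost]
    other_event_costs: dict[str, OtherEventCost]
    exchange_rate_dkk_per_eur: float = 7.46
    price_year: int = 2024
    price_multiplier: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _keys(self) -> "CostSchedule":
        missing = set(STAGE_COST_KEYS) - set(self.stage_costs)
        if missing:
            raise ValueError(f"stage_costs missing {sorted(missing)}")
        missing_cvd = set(CVD_EVENT_NAMES) - set(self.cvd_event_costs)
        if missing_cvd:
            raise ValueError(f"cvd_event_costs missing {sorted(missing_cvd)}")
        return self

    def stage_point_vector(self) -> np.ndarray:
        return np.array([self.stage_costs[k].point for k in STAGE_COST_KEYS])

    def state_cost_vector(self, state_codes: np.ndarray) -> np.ndarray:
        """Annual state cost per patient (0 for DEAD)."""
        codes = np.asarray(state_codes)
        out = np.zeros(codes.shape, dtype=float)
        grid = codes < 18
        out[grid] = self.stage_point_vector()[codes[grid] // 3]
        out[codes == int(HealthState.HEMODIALYSIS)] = self.hemodialysis_annual
        out[codes == int(HealthState.PERITONEAL_DIALYSIS)] = self.peritoneal_dialysis.point
        out[codes == int(HealthState.TRANSPLANT)] = (
            self.transplant.point + self.immunosuppression_annual
        )
        return out


class UtilitySchedule(BaseModel):
    """State utilities, an age-utility curve, and one-time disutilities."""

    #: utilities for G1..G5 (index 0..5)
    g_utilities: list[float]
    hemodialysis: float = Field(0.57, ge=0, le=1)
    peritoneal_dialysis: float = Field(0.62, ge=0, le=1)
    transplant: float = Field(0.73, ge=0, le=1)
    #: age-specific utility of the general population, multiplicative
    age_grid: list[float]
    age_utility: list[float]
    event_disutilities: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "UtilitySchedule":
        if len(self.g_utilities) != 6:
            raise ValueError("g_utilities must have 6 entries")
        if any(not 0 <= u <= 1 for u in self.g_utilities):
            raise ValueError("state utilities must lie in [0, 1]")
        if len(self.age_grid) != len(self.age_utility):
            raise ValueError("age_grid and age_utility lengths differ")
        if any(not 0 <= u <= 1 for u in self.age_utility):
            raise ValueError("age utilities must lie in [0, 1]")
        if any(d < 0 for d in self.event_disutilities.values()):
            raise ValueError("disutilities must be >= 0")
        return self

    def age_adjustment(self, age: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(age, dtype=float), self.age_grid, self.age_utility)

    def state_utility_vector(self, state_codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(state_codes)
        out = np.zeros(codes.shape, dtype=float)
        grid = codes < 18
        out[grid] = np.asarray(self.g_utilities)[codes[grid] // 3]
        out[codes == int(HealthState.HEMODIALYSIS)] = self.hemodialysis
        out[codes == int(HealthState.PERITONEAL_DIALYSIS)] = self.peritoneal_dialysis
        out[codes == int(HealthState.TRANSPLANT)] = self.transplant
        return out


@dataclasses.dataclass
class PatientYearRecord:
    """What one patient experienced in one model year, for accrual."""

    state: HealthState
    age: float
    on_sglt2i: bool = False
    #: events occurring this cycle -> count
    events: Mapping[str, int] = dataclasses.field(default_factory=dict)
    #: CVD event types from *previous* cycles (drive follow-up costs)
    prior_cvd_events: frozenset[str] = frozenset()
    #: chronic conditions with annual-timing costs already established
    chronic_cost_flags: frozenset[str] = frozenset()
    #: events occurring this cycle for the first time (first-year timing)
    first_occurrences: frozenset[str] = frozenset()


def accrue_annual_cost(record: PatientYearRecord, schedule: CostSchedule) -> float:
    """Total EUR accrued by one patient-year.  Dead patient-years cost 0."""
    if record.state == HealthState.DEAD:
        return 0.0
    total = float(schedule.state_cost_vector(np.array([int(record.state)]))[0])
    if record.on_sglt2i:
        total += schedule.sglt2i_annual * schedule.price_multiplier
    else:
        total += schedule.soc_annual
    for ev, n in record.events.items():
        if n == 0:
            continue
        if ev in schedule.cvd_event_costs:
            total += schedule.cvd_event_costs[ev].acute * n
        elif ev in schedule.other_event_costs:
            oc = schedule.other_event_costs[ev]
            if oc.timing == "per_event":
                total += oc.amount * n
            elif oc.timing == "first_year":
                if ev in record.first_occurrences:
                    total += oc.amount
            # annual timing handled below via chronic_cost_flags
        else:
            raise ScheduleLookupError(f"no cost entry for event {ev!r}")
    for ev in record.prior_cvd_events:
        total += schedule.cvd_event_costs[ev].followup_annual
    for ev in record.chronic_cost_flags:
        oc = schedule.other_event_costs.get(ev)
        if oc is None:
            raise ScheduleLookupError(f"no cost entry for chronic flag {ev!r}")
        if oc.timing == "annual":
            total += oc.amount
    return total


def accrue_qalys(record: PatientYearRecord, schedule: UtilitySchedule) -> float:
    """QALYs accrued by one patient-year, floored at zero; dead -> 0."""
    if record.state == HealthState.DEAD:
        return 0.0
    base = float(schedule.state_utility_vector(np.array([int(record.state)]))[0])
    q = base * float(schedule.age_adjustment(record.age))
    for ev, n in record.events.items():
        q -= schedule.event_disutilities.get(ev, 0.0) * n
    return max(q, 0.0)


@dataclasses.dataclass
class ScenarioComparison:
    """Incremental economics of a comparator uptake vs a reference uptake."""

    delta_qaly: float
    delta_cost: float
    savings_by_category: dict[str, float]
    lam: float
    nmb: float

    def as_dict(self) -> dict[str, float]:
        d = {"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost,
             "lambda": self.lam, "nmb": self.nmb}
        d.update({f"savings_{k}": v for k, v in self.savings_by_category.items()})
        return d


def net_monetary_benefit(delta_qaly: float, delta_cost: float, lam: float = DEFAULT_LAMBDA) -> float:
    """``NMB = lambda * dQALY - dCost`` (exact identity)."""
    return lam * delta_qaly - delta_cost


def compute_savings(
    reference_costs: Mapping[str, float], comparator_costs: Mapping[str, float]
) -> dict[str, float]:
    """Per-category savings = reference cost - comparator cost."""
    if set(reference_costs) != set(comparator_costs):
        raise ContractViolationError("cost category keys do not match")
    return {k: reference_costs[k] - comparator_costs[k] for k in reference_costs}


_COST_CATEGORIES = ("cost_krt", "cost_cvd", "cost_stage", "cost_drug", "cost_other")


def compare_scenarios(
    reference: pd.DataFrame,
    comparator: pd.DataFrame,
    lam: float = DEFAULT_LAMBDA,
    cost_categories: Sequence[str] = _COST_CATEGORIES,
) -> ScenarioComparison:
    """Incremental QALYs, costs, category savings and NMB between two
    per-year outcome series simulated on the same horizon and scale."""
    if len(reference) != len(comparator):
        raise ContractViolationError("scenario horizons differ")
    delta_qaly = float(comparator["qalys"].sum() - reference["qalys"].sum())
    delta_cost = float(comparator["cost_total"].sum() - reference["cost_total"].sum())
    savings = {
        cat: float(reference[cat].sum() - comparator[cat].sum())
        for cat in cost_categories
        if cat in reference.columns
    }
    savings["total"] = float(reference["cost_total"].sum() - comparator["cost_total"].sum())
    return ScenarioComparison(
        delta_qaly=delta_qaly,
        delta_cost=delta_cost,
        savings_by_category=savings,
        lam=lam,
        nmb=net_monetary_benefit(delta_qaly, delta_cost, lam),
    )
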