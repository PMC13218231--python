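"""Annual stochastic events: death, kidney failure / KRT, and complications.

Mortality is modelled as an age-indexed baseline hazard multiplied by a
relative-risk grid over the KDIGO (G, A) categories - death risk is a
function of eGFR and albuminuria - times a global calibration multiplier.
The grid is validated monotone: risk never decreases with a worse G or A
category.

Complication probabilities are log-linear in age, treated-effective SBP and
HbA1c, the G category and comorbidity flags; the annual probability is
``1 - exp(-exp(lp))`` so it is a valid probability for any coefficients.
Treatment status is structurally excluded as a covariate: SGLT2i benefit on
events flows only through the mediated markers.

Kidney failure is defined as entry into G5; while in G5 a configurable
annual probability triggers KRT initiation, with the modality drawn from the
registry initiation split.  Transitions between KRT modalities (and to
death) follow a validated row-stochastic matrix with constant transplant
probabilities.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ContractViolationError, DomainError
from .states import HealthState

KRT_LABELS = ("hemodialysis", "peritoneal_dialysis", "transplant")
_KRT_CODE = {
    "hemodialysis": int(HealthState.HEMODIALYSIS),
    "peritoneal_dialysis": int(HealthState.PERITONEAL_DIALYSIS),
    "transplant": int(HealthState.TRANSPLANT),
}

EVENT_NAMES = (
    "mace",
    "new_hf",
    "cvd_hosp",
    "aki",
    "anemia",
    "mbd",
    "new_diabetes",
    "new_hypertension",
    "infection",
    "other_ae",
)
CVD_EVENT_NAMES = ("mace", "new_hf", "cvd_hosp")


class MortalitySurface(BaseModel):
    """Annual all-cause mortality as f(age, G category, A category)."""

    age_grid: list[float]
    baseline_annual_hazard: list[float]
    #: 6 x 3 grid of multipliers, rows G1..G5, columns A1..A3
    relative_risk_grid: list[list[float]]
    calibration_multiplier: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _validate(self) -> "MortalitySurface":
        if len(self.age_grid) != len(self.baseline_annual_hazard):
            raise ValueError("age_grid and baseline_annual_hazard lengths differ")
        if any(h < 0 for h in self.baseline_annual_hazard):
            raise ValueError("baseline hazards must be >= 0")
        g = np.asarray(self.relative_risk_grid, dtype=float)
        if g.shape != (6, 3):
            raise ValueError("relative_risk_grid must be 6 x 3 (G1..G5 x A1..A3)")
        if np.any(g < 0):
            raise ValueError("relative risks must be >= 0")
        if np.any(np.diff(g, axis=0) < -1e-12) or np.any(np.diff(g, axis=1) < -1e-12):
            raise ValueError("relative_risk_grid must be non-decreasing in worse G and A")
        return self

    def baseline(self, age: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(age, dtype=float), self.age_grid, self.baseline_annual_hazard)

    def rr(self, state_codes: np.ndarray) -> np.ndarray:
        grid = np.asarray(self.relative_risk_grid, dtype=float)
        codes = np.asarray(state_codes)
        return grid[codes // 3, codes % 3]


def annual_death_probability(
    age: np.ndarray | float,
    state: np.ndarray | HealthState,
    surface: MortalitySurface,
) -> np.ndarray | float:
    """``1 - exp(-baseline(age) * RR(G, A) * calibration)`` for grid states.

    KRT states carry their own hazards in :class:`KrtTransitionMatrix` and
    are rejected here, as is DEAD.
    """
    scalar = np.isscalar(age) and isinstance(state, HealthState)
    codes = np.atleast_1d(np.asarray(state, dtype=np.int64))
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(codes >= 18):
        raise ContractViolationError("annual_death_probability applies to grid states only")
    hazard = surface.baseline(ages) * surface.rr(codes) * surface.calibration_multiplier
    p = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    return float(p[0]) if scalar else p


class KrtTransitionMatrix(BaseModel):
    """KRT initiation split and annual transitions among modalities/death."""

    initiation_split: dict[str, float]
    #: per-modality rows; missing mass = stay in current modality
    transitions: dict[str, dict[str, float]]
    #: annual probability of KRT initiation while in G5
    initiation_probability: float = Field(0.35, ge=0, le=1)
    #: whether graft failure may return a transplanted patient to dialysis
    allow_graft_failure: bool = True

    @field_validator("initiation_split")
    @classmethod
    def _split(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(KRT_LABELS):
            raise ValueError(f"initiation_split keys must be {KRT_LABELS}")
        if any(p < 0 for p in v.values()):
            raise ValueError("initiation_split entries must be >= 0")
        total = sum(v.values())
        if total <= 0:
            raise ValueError("initiation_split sums to zero")
        return {k: v[k] / total for k in KRT_LABELS}

    @model_validator(mode="after")
    def _rows(self) -> "KrtTransitionMatrix":
        allowed = set(KRT_LABELS) | {"dead"}
        for row_key in KRT_LABELS:
            row = self.transitions.get(row_key)
            if row is None:
                raise ValueError(f"transitions missing row {row_key!r}")
            unknown = set(row) - allowed
            if unknown:
                raise ValueError(f"transitions[{row_key}]: unknown targets {sorted(unknown)}")
            if any(not 0 <= p <= 1 for p in row.values()):
                raise ValueError(f"transitions[{row_key}]: probabilities outside [0, 1]")
            if sum(row.values()) > 1 + 1e-12:
                raise ValueError(f"transitions[{row_key}]: row sum exceeds 1")
        return self

    def split_cumulative(self) -> np.ndarray:
        return np.cumsum([self.initiation_split[k] for k in KRT_LABELS])

    def row_targets_and_cum(self, modality: str) -> tuple[list[int], np.ndarray]:
        """Transition targets (state codes) and cumulative probabilities."""
        row = dict(self.transitions[modality])
        if modality == "transplant" and not self.allow_graft_failure:
            row.pop("hemodialysis", None)
            row.pop("peritoneal_dialysis", None)
        targets, probs = [], []
        for key, p in row.items():
            targets.append(int(HealthState.DEAD) if key == "dead" else _KRT_CODE[key])
            probs.append(p)
        return targets, np.cumsum(probs)


def krt_annual_transition(
    state_codes: np.ndarray, matrix: KrtTransitionMatrix, u: np.ndarray
) -> np.ndarray:
    """Vectorised one-year KRT modality transition given uniforms ``u``.

    Patients whose uniform lands beyond the row's cumulative mass stay in
    their current modality.  DEAD is absorbing (dead codes pass through).
    """
    original = np.asarray(state_codes)
    codes = original.copy()
    for modality in KRT_LABELS:
        # masks come from the entry states: exactly one transition per year
        mask = original == _KRT_CODE[modality]
        if not mask.any():
            continue
        targets, cum = matrix.row_targets_and_cum(modality)
        uu = np.asarray(u)[mask]
        idx = np.searchsorted(cum, uu, side="right")
        new = codes[mask]
        moved = idx < len(targets)
        new[moved] = np.asarray(targets, dtype=codes.dtype)[idx[moved]]
        codes[mask] = new
    return codes


class EventModel(BaseModel):
    """Log-linear annual probability model for one complication."""

    intercept: float
    age_per_year: float = 0.0
    sbp_per_10mmhg: float = 0.0
    hba1c_per_unit: float = 0.0
    #: additive log-rate offsets for G1..G5 (KRT states use the G5 offset)
    g_offsets: list[float] = Field(default_factory=lambda: [0.0] * 6)
    diabetes: float = 0.0
    cvd: float = 0.0
    chf: float = 0.0
    hypertension: float = 0.0

    @field_validator("g_offsets")
    @classmethod
    def _six(cls, v: list[float]) -> list[float]:
        if len(v) != 6:
            raise ValueError("g_offsets must have 6 entries (G1..G5)")
        return v


class EventRates(BaseModel):
    """Per-event annual probability models plus shared covariate references."""

    models: dict[str, EventModel]
    ref_age: float = 75.0
    ref_sbp: float = 132.0
    ref_hba1c: float = 5.9

    @field_validator("models")
    @classmethod
    def _known_events(cls, v: dict[str, EventModel]) -> dict[str, EventModel]:
        unknown = set(v) - set(EVENT_NAMES)
        if unknown:
            raise ValueError(f"unknown event models {sorted(unknown)}")
        missing = set(EVENT_NAMES) - set(v)
        if missing:
            raise ValueError(f"missing event models {sorted(missing)}")
        return v

    def probability(
        self,
        event: str,
        state_codes: np.ndarray,
        age: np.ndarray,
        sbp: np.ndarray,
        hba1c: np.ndarray,
        has_diabetes: np.ndarray,
        has_cvd: np.ndarray,
        has_chf: np.ndarray,
        has_hypertension: np.ndarray,
    ) -> np.ndarray:
        """Evaluate the annual event probability per patient."""
        m = self.models[event]
        codes = np.asarray(state_codes)
        g_idx = np.where(codes < 18, codes // 3, 5)  # KRT treated as G5 severity
        offs = np.asarray(m.g_offsets)[g_idx]
        lp = (
            m.intercept
            + m.age_per_year * (np.asarray(age) - self.ref_age)
            + m.sbp_per_10mmhg * (np.asarray(sbp) - self.ref_sbp) / 10.0
            + m.hba1c_per_unit * (np.asarray(hba1c) - self.ref_hba1c)
            + offs
            + m.diabetes * np.asarray(has_diabetes)
            + m.cvd * np.asarray(has_cvd)
            + m.chf * np.asarray(has_chf)
            + m.hypertension * np.asarray(has_hypertension)
        )
        return 1.0 - np.exp(-np.exp(lp))


def sample_events(
    rates: EventRates,
    events: Iterable[str],
    uniforms: dict[str, np.ndarray],
    **covariates: np.ndarray,
) -> dict[str, np.ndarray]:
    """Independent Bernoulli draws per event type at evaluated probabilities.

    ``uniforms[event]`` supplies the per-patient uniform stream for that
    hazard, enabling common-random-number comparisons across scenarios.
    """
    out = {}
    for ev in events:
        p = rates.probability(ev, **covariates)
        out[ev] = uniforms[ev] < p
    return out


def check_kidney_failure_threshold(egfr: float, kf_threshold: float = 15.0) -> bool:
    """True if the eGFR value is below the kidney-failure (G5) threshold."""
    if egfr <= 0:
        raise DomainError("egfr must be positive")
    return egfr < kf_threshold
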