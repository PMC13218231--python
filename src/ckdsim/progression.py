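"""Annual CKD progression dynamics and the SGLT2 inhibitor treatment layer.

Disease progression is driven by a covariate-adjusted linear annual eGFR
slope (with optional patient-level Gaussian heterogeneity) and a
multiplicative annual UACR growth.  The treatment effect is *fully mediated*
through the disease markers: while on treatment the chronic eGFR slope is
multiplied by ``chronic_slope_multiplier`` (< 1 means slower decline), a
one-time acute haemodynamic eGFR dip is applied at initiation (and reversed
on discontinuation), UACR is relatively reduced, and SBP/HbA1c are shifted.
Treatment status itself never enters any downstream risk equation.

Upon discontinuation the patient reverts to natural progression with no
residual effect: the reversible components (dip, UACR/SBP/HbA1c shifts)
are removed, while eGFR ground already lost or preserved remains - that is
the natural history of a slope-mediated effect.

``effect_scale`` scales every component of the effect; 0 reproduces the
untreated trajectory exactly, 1 is the base case and 0.8 the reduced-effect
sensitivity analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .cohort import PatientProfile
from .errors import ContractViolationError, EligibilityError
from .states import HealthState, a_index, classify_codes

#: G-category indices eligible for SGLT2i initiation (G3a, G3b, G4);
#: G5 is excluded because trial effects were not applied to stage 5.
ELIGIBLE_G_INDICES = (2, 3, 4)


class SlopeModifiers(BaseModel):
    """Additive contributions (mL/min/1.73 m^2/year) to the annual eGFR slope.

    Negative values steepen decline.  Continuous covariates are centred at
    the reference values so the baseline slope is interpretable as the slope
    of a reference patient.
    """

    age_per_decade: float = -0.15
    diabetes: float = -0.6
    hypertension: float = -0.2
    sbp_per_10mmhg: float = -0.15
    hba1c_per_unit: float = -0.2
    uacr_a2: float = -0.4
    uacr_a3: float = -1.2
    ref_age: float = 75.0
    ref_sbp: float = 132.0
    ref_hba1c: float = 5.9


class ProgressionParameters(BaseModel):
    """Natural-history parameters of the progression model."""

    baseline_egfr_slope: float = Field(-2.0, lt=0)
    #: SD of the patient-level Gaussian slope random effect
    slope_sd: float = Field(0.8, ge=0)
    slope_modifiers: SlopeModifiers = Field(default_factory=SlopeModifiers)
    #: relative UACR change per year (0.04 = +4 %/year)
    uacr_annual_growth: float = 0.04
    sbp_annual_drift: float = 0.3
    hba1c_annual_drift: float = 0.01
    egfr_floor: float = Field(2.0, gt=0)
    uacr_cap: float = Field(5000.0, gt=0)


class TreatmentEffect(BaseModel):
    """SGLT2 inhibitor effect parameters (trial-derived assumptions)."""

    chronic_slope_multiplier: float = Field(0.5, ge=0, le=1)
    acute_egfr_dip: float = Field(2.0, ge=0)
    uacr_relative_reduction: float = Field(0.30, ge=0, le=1)
    sbp_reduction: float = Field(2.6, ge=0)
    hba1c_reduction: float = Field(0.1, ge=0)
    annual_discontinuation_probability: float = Field(0.05, ge=0, le=1)
    adverse_event_rates: dict[str, float] = Field(
        default_factory=lambda: {"treatment_adverse_event": 0.01}
    )
    effect_scale: float = Field(1.0, ge=0, le=1)

    @field_validator("adverse_event_rates")
    @classmethod
    def _rates_are_probs(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"adverse_event_rates[{k}] outside [0, 1]")
        return v

    # ---- effect components after applying the global scale ----

    @property
    def scaled_slope_multiplier(self) -> float:
        return 1.0 - self.effect_scale * (1.0 - self.chronic_slope_multiplier)

    @property
    def scaled_dip(self) -> float:
        return self.effect_scale * self.acute_egfr_dip

    @property
    def scaled_uacr_factor(self) -> float:
        return 1.0 - self.effect_scale * self.uacr_relative_reduction

    @property
    def scaled_sbp_reduction(self) -> float:
        return self.effect_scale * self.sbp_reduction

    @property
    def scaled_hba1c_reduction(self) -> float:
        return self.effect_scale * self.hba1c_reduction


def covariate_slope(
    params: ProgressionParameters,
    age: np.ndarray,
    sbp: np.ndarray,
    hba1c: np.ndarray,
    uacr: np.ndarray,
    has_diabetes: np.ndarray,
    has_hypertension: np.ndarray,
    slope_re: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Untreated annual eGFR slope per patient (always <= 0).

    The clamp at zero encodes the default assumption that natural dynamics
    never raise eGFR, even for a patient whose random effect would otherwise
    flip the sign.
    """
    m = params.slope_modifiers
    a_idx = a_index(uacr)
    slope = (
        params.baseline_egfr_slope
        + m.age_per_decade * (np.asarray(age) - m.ref_age) / 10.0
        + m.diabetes * np.asarray(has_diabetes)
        + m.hypertension * np.asarray(has_hypertension)
        + m.sbp_per_10mmhg * (np.asarray(sbp) - m.ref_sbp) / 10.0
        + m.hba1c_per_unit * (np.asarray(hba1c) - m.ref_hba1c)
        + m.uacr_a2 * (a_idx == 1)
        + m.uacr_a3 * (a_idx == 2)
        + slope_re
    )
    return np.minimum(slope, 0.0)


def effective_uacr(uacr, on_treatment, effect: TreatmentEffect | None):
    """UACR after the (reversible) treatment reduction, where applicable."""
    if effect is None:
        return np.asarray(uacr, dtype=float)
    return np.where(on_treatment, np.asarray(uacr) * effect.scaled_uacr_factor, uacr)


def annual_update(
    patient: PatientProfile,
    params: ProgressionParameters,
    effect: TreatmentEffect | None = None,
    slope_re: float = 0.0,
) -> PatientProfile:
    """Advance a single alive, non-KRT patient by one model year.

    Ages the patient, applies the covariate-adjusted eGFR slope (multiplied
    by the chronic slope multiplier while on treatment), grows UACR, drifts
    SBP/HbA1c, and reclassifies the health state from the updated markers
    (using treatment-effective UACR where applicable).  The acute dip is
    *not* applied here - it belongs to :func:`initiate_treatment`.
    """
    if patient.state == HealthState.DEAD or patient.state.is_krt:
        raise ContractViolationError(
            f"annual_update requires an alive non-KRT patient, got {patient.state.name}"
        )
    on_trt = patient.on_sglt2i and effect is not None
    sbp = patient.sbp + params.sbp_annual_drift
    hba1c = patient.hba1c + params.hba1c_annual_drift
    eff_sbp = sbp - (effect.scaled_sbp_reduction if on_trt else 0.0)
    eff_hba1c = hba1c - (effect.scaled_hba1c_reduction if on_trt else 0.0)
    eff_uacr_now = patient.uacr * (effect.scaled_uacr_factor if on_trt else 1.0)

    slope = covariate_slope(
        params,
        np.array([patient.age]),
        np.array([eff_sbp]),
        np.array([eff_hba1c]),
        np.array([eff_uacr_now]),
        np.array([patient.has_diabetes]),
        np.array([patient.has_hypertension]),
        slope_re,
    )[0]
    mult = effect.scaled_slope_multiplier if on_trt else 1.0
    egfr = max(patient.egfr + slope * mult, params.egfr_floor)
    uacr = min(patient.uacr * (1.0 + params.uacr_annual_growth), params.uacr_cap)
    eff_uacr_new = uacr * (effect.scaled_uacr_factor if on_trt else 1.0)
    state = HealthState(int(classify_codes(np.array([egfr]), np.array([eff_uacr_new]))[0]))

    return PatientProfile(
        **{
            **patient.__dict__,
            "age": patient.age + 1,
            "egfr": egfr,
            "uacr": uacr,
            "sbp": sbp,
            "hba1c": hba1c,
            "state": state,
        }
    )


def initiate_treatment(patient: PatientProfile, effect: TreatmentEffect) -> PatientProfile:
    """Start SGLT2i treatment: flag the patient and apply the acute dip once.

    Only grid states G3a-G4 are eligible; G5, KRT and DEAD raise
    :class:`EligibilityError`.  Re-initiating an already treated patient is
    an idempotent no-op with a warning.
    """
    if patient.on_sglt2i:
        warnings.warn(f"patient {patient.id} already on SGLT2i; no-op", stacklevel=2)
        return patient
    if (
        patient.state == HealthState.DEAD
        or patient.state.is_krt
        or patient.state // 3 not in ELIGIBLE_G_INDICES
    ):
        raise EligibilityError(
            f"state {patient.state.name} is not eligible for SGLT2i initiation"
        )
    egfr = max(patient.egfr - effect.scaled_dip, 0.1)
    eff_uacr = patient.uacr * effect.scaled_uacr_factor
    state = HealthState(int(classify_codes(np.array([egfr]), np.array([eff_uacr]))[0]))
    return PatientProfile(**{**patient.__dict__, "on_sglt2i": True, "egfr": egfr, "state": state})


def maybe_discontinue(
    patient: PatientProfile, effect: TreatmentEffect, rng: np.random.Generator
) -> PatientProfile:
    """Bernoulli discontinuation draw; on stopping, the reversible effect
    components are removed and all subsequent dynamics are untreated."""
    if not patient.on_sglt2i:
        return patient
    if rng.random() >= effect.annual_discontinuation_probability:
        return patient
    egfr = patient.egfr + effect.scaled_dip
    state = HealthState(int(classify_codes(np.array([egfr]), np.array([patient.uacr]))[0]))
    return PatientProfile(**{**patient.__dict__, "on_sglt2i": False, "egfr": egfr, "state": state})
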