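"""Synthetic patient cohorts matching published Danish CKD G3-G5 marginals.

The national registry data behind the model are available only as marginal
summaries (means, stage shares, comorbidity prevalences).  This module
generates individual-level cohorts whose marginal distributions match those
summaries:

* CKD stage is sampled first from the printed stage distribution, then eGFR
  uniformly within that stage's KDIGO bounds, then the whole cohort is
  mean-shifted (clipped within bounds) toward the printed mean eGFR.  This
  guarantees stage/eGFR consistency, which the progression model requires.
* UACR is lognormal with the printed mean (right-skewed, positive);
  albuminuria categories follow from the KDIGO thresholds.
* Other continuous risk factors are truncated normals with configurable
  spreads; comorbidity flags are independent Bernoulli draws at the printed
  prevalences.

All spreads live in :class:`Dispersion` so alternative distributional
assumptions cost one config edit.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats

from .errors import DomainError
from .states import HealthState, classify_codes, state_egfr_bounds

STAGE_KEYS = ("G3a", "G3b", "G4", "G5")
COMORBIDITY_KEYS = ("diabetes", "cvd", "hypertension", "chf")

#: numerical margin kept inside stage bounds when mean-shifting eGFR
_EDGE_MARGIN = 0.05
#: eGFR lower bound used when sampling within G5 (KDIGO bound is 0)
_G5_SAMPLING_FLOOR = 4.0


class Dispersion(BaseModel):
    """Spread parameters for the continuous risk factors.

    The source tables print means only; these defaults are the package's
    documented distributional assumptions (see docs/methods.md).
    """

    age_sd: float = Field(10.0, ge=0)
    bmi_sd: float = Field(5.0, ge=0)
    sbp_sd: float = Field(15.0, ge=0)
    cholesterol_sd: float = Field(35.0, ge=0)
    hba1c_sd: float = Field(0.8, ge=0)
    #: lognormal shape parameter (sigma of log UACR)
    uacr_sigma: float = Field(0.9, ge=0)


class CohortSpec(BaseModel):
    """Marginal description of a prevalent or incident CKD G3-G5 cohort."""

    population_label: Literal["prevalent", "incident"]
    n_patients: int = Field(ge=1)
    mean_age: float = Field(gt=0)
    pct_male: float = Field(ge=0, le=1)
    mean_egfr: float = Field(gt=0)
    mean_uacr: float = Field(gt=0)
    mean_hba1c: float = Field(gt=0)
    mean_bmi: float = Field(gt=0)
    mean_cholesterol: float = Field(gt=0)
    mean_sbp: float = Field(gt=0)
    stage_distribution: dict[str, float]
    comorbidity_prevalence: dict[str, float]
    dispersion: Dispersion = Field(default_factory=Dispersion)

    @field_validator("stage_distribution")
    @classmethod
    def _normalize_stages(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(STAGE_KEYS)
        if unknown:
            raise ValueError(f"stage_distribution: unknown stages {sorted(unknown)}")
        if any(p < 0 for p in v.values()):
            raise ValueError("stage_distribution: negative share")
        total = sum(v.values())
        if total <= 0:
            raise ValueError("stage_distribution: shares sum to zero, not normalizable")
        return {k: v.get(k, 0.0) / total for k in STAGE_KEYS}

    @field_validator("comorbidity_prevalence")
    @classmethod
    def _check_comorbidities(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(COMORBIDITY_KEYS)
        if unknown:
            raise ValueError(f"comorbidity_prevalence: unknown keys {sorted(unknown)}")
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"comorbidity_prevalence: {k} outside [0, 1]")
        return {k: v.get(k, 0.0) for k in COMORBIDITY_KEYS}

    @model_validator(mode="after")
    def _stage_sum(self) -> "CohortSpec":
        assert abs(sum(self.stage_distribution.values()) - 1.0) < 1e-9
        return self


@dataclasses.dataclass
class PatientProfile:
    """One simulated person at a point in time."""

    id: int
    age: float
    male: bool
    egfr: float
    uacr: float
    hba1c: float
    bmi: float
    cholesterol: float
    sbp: float
    has_diabetes: bool
    has_cvd: bool
    has_hypertension: bool
    has_chf: bool
    on_sglt2i: bool
    state: HealthState
    entry_year: int

    def __post_init__(self) -> None:
        if self.egfr <= 0 or self.uacr <= 0:
            raise DomainError("egfr and uacr must be positive")
        if not 18 <= self.age <= 110:
            raise DomainError("age must be in [18, 110]")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Truncated normal whose *truncated* mean equals ``mean``.

    Truncation shifts the mean of a clipped normal, so the location
    parameter is adjusted by fixed-point iteration until the analytic
    truncated mean matches the target.
    """
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    loc = mean
    for _ in range(8):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        achieved = stats.truncnorm.mean(a, b, loc=loc, scale=sd)
        if abs(achieved - mean) < 1e-6:
            break
        loc -= achieved - mean
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def sample_uacr(mean_uacr: float, sigma: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Lognormal UACR sample whose expectation equals ``mean_uacr``."""
    if mean_uacr <= 0:
        raise DomainError("mean_uacr must be positive")
    if sigma == 0:
        return np.full(n, mean_uacr)
    mu = np.log(mean_uacr) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, n)


def assign_albuminuria_category(
    mean_uacr: float, dispersion: Dispersion | float, seed: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-patient UACR values and their A-category labels.

    ``dispersion`` may be a :class:`Dispersion` or a bare lognormal sigma.
    Returns ``(uacr_values, labels)`` with labels in {"A1", "A2", "A3"}.
    """
    sigma = dispersion.uacr_sigma if isinstance(dispersion, Dispersion) else float(dispersion)
    rng = np.random.default_rng(seed)
    uacr = sample_uacr(mean_uacr, sigma, rng, n)
    a_idx = np.where(uacr < 30.0, 0, np.where(uacr <= 300.0, 1, 2))
    labels = np.array(["A1", "A2", "A3"])[a_idx]
    return uacr, labels


def _sample_stage_consistent_egfr(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample stages and within-stage eGFR, then mean-shift toward the target.

    The shift is applied iteratively with clipping at the stage bounds, so the
    achieved mean is the closest *feasible* mean to ``spec.mean_egfr`` given
    the stage distribution (the printed mean and stage shares need not be
    jointly feasible).
    """
    n = spec.n_patients
    probs = np.array([spec.stage_distribution[k] for k in STAGE_KEYS])
    stage_idx = rng.choice(len(STAGE_KEYS), size=n, p=probs)
    lo = np.empty(n)
    hi = np.empty(n)
    for i, key in enumerate(STAGE_KEYS):
        b_lo, b_hi = state_egfr_bounds(key)
        mask = stage_idx == i
        lo[mask] = max(b_lo, _G5_SAMPLING_FLOOR) if key == "G5" else b_lo
        hi[mask] = b_hi
    egfr = rng.uniform(lo, hi)
    for _ in range(60):
        delta = spec.mean_egfr - egfr.mean()
        if abs(delta) < 1e-4:
            break
        egfr = np.clip(egfr + delta, lo + _EDGE_MARGIN, hi - _EDGE_MARGIN)
    return stage_idx, egfr


def generate_cohort(
    spec: CohortSpec, seed: int, entry_year: int = 1, id_offset: int = 0
) -> pd.DataFrame:
    """Generate ``spec.n_patients`` synthetic patients, one row each.

    Deterministic for a fixed ``seed``.  The returned frame carries one
    column per :class:`PatientProfile` field, with ``state`` as the integer
    :class:`~ckdsim.states.HealthState` code consistent with the sampled
    eGFR and UACR.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    d = spec.dispersion

    _, egfr = _sample_stage_consistent_egfr(spec, rng)
    uacr = sample_uacr(spec.mean_uacr, d.uacr_sigma, rng, n)

    age = _truncated_normal(rng, spec.mean_age, d.age_sd, 18.0, 110.0, n)
    bmi = _truncated_normal(rng, spec.mean_bmi, d.bmi_sd, 14.0, 60.0, n)
    sbp = _truncated_normal(rng, spec.mean_sbp, d.sbp_sd, 80.0, 230.0, n)
    chol = _truncated_normal(rng, spec.mean_cholesterol, d.cholesterol_sd, 80.0, 400.0, n)
    hba1c = _truncated_normal(rng, spec.mean_hba1c, d.hba1c_sd, 3.5, 14.0, n)

    male = rng.random(n) < spec.pct_male
    com = {k: rng.random(n) < spec.comorbidity_prevalence[k] for k in COMORBIDITY_KEYS}

    frame = pd.DataFrame(
        {
            "id": np.arange(id_offset, id_offset + n, dtype=np.int64),
            "age": age,
            "male": male,
            "egfr": egfr,
            "uacr": uacr,
            "hba1c": hba1c,
            "bmi": bmi,
            "cholesterol": chol,
            "sbp": sbp,
            "has_diabetes": com["diabetes"],
            "has_cvd": com["cvd"],
            "has_hypertension": com["hypertension"],
            "has_chf": com["chf"],
            "on_sglt2i": np.zeros(n, dtype=bool),
            "state": classify_codes(egfr, uacr),
            "entry_year": np.full(n, entry_year, dtype=np.int64),
        }
    )
    return frame


def profile_from_row(row: pd.Series) -> PatientProfile:
    """Materialise a :class:`PatientProfile` from a cohort frame row."""
    return PatientProfile(
        id=int(row["id"]),
        age=float(row["age"]),
        male=bool(row["male"]),
        egfr=float(row["egfr"]),
        uacr=float(row["uacr"]),
        hba1c=float(row["hba1c"]),
        bmi=float(row["bmi"]),
        cholesterol=float(row["cholesterol"]),
        sbp=float(row["sbp"]),
        has_diabetes=bool(row["has_diabetes"]),
        has_cvd=bool(row["has_cvd"]),
        has_hypertension=bool(row["has_hypertension"]),
        has_chf=bool(row["has_chf"]),
        on_sglt2i=bool(row["on_sglt2i"]),
        state=HealthState(int(row["state"])),
        entry_year=int(row["entry_year"]),
    )


#: column dictionary written alongside cohort CSVs
COLUMN_DICTIONARY = {
    "id": "patient identifier (stable across scenario arms)",
    "age": "age in years",
    "male": "True if male",
    "egfr": "estimated glomerular filtration rate, mL/min/1.73 m^2",
    "uacr": "urinary albumin-creatinine ratio, mg/g",
    "hba1c": "glycated hemoglobin, %",
    "bmi": "body mass index, kg/m^2",
    "cholesterol": "total serum cholesterol, mg/dL",
    "sbp": "systolic blood pressure, mm Hg",
    "has_diabetes": "diabetes comorbidity flag",
    "has_cvd": "cardiovascular disease comorbidity flag",
    "has_hypertension": "hypertension comorbidity flag",
    "has_chf": "congestive heart failure comorbidity flag",
    "on_sglt2i": "currently on SGLT2 inhibitor",
    "state": "KDIGO health state code (see ckdsim.states.HealthState)",
    "entry_year": "model cycle (1-based) in which the patient enters",
}


def write_cohort_csv(frame: pd.DataFrame, path: str, seed: int) -> None:
    """Write a cohort with the generating seed recorded in header metadata."""
    buf = io.StringIO()
    buf.write(f"# ckdsim cohort; seed={seed}; n={len(frame)}\n")
    for col, desc in COLUMN_DICTIONARY.items():
        buf.write(f"# {col}: {desc}\n")
    frame.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
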