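"""Scenario orchestration, accumulated report tables, sensitivity presets,
KRT capacity flags and the reproducibility manifest."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator

from .calibration import calibrate_mortality
from .config import ParameterBundle
from .population import ScenarioConfig, ScenarioResult, run_uptake_scenarios

BASE_UPTAKES = (0.15, 0.50, 0.90)
REPORT_YEAR_INDICES = (1, 6, 10)

#: accumulated report rows -> (per-year outcome column, kind)
TABLE_ROWS = [
    ("Eligible patients with CKD", "eligible", "level"),
    ("MACE", "mace", "count"),
    ("New onset HF", "new_hf", "count"),
    ("CVD hospitalization", "cvd_hosp", "count"),
    ("KF + KRT", "kf_or_krt", "count"),
    ("Hemodialysis", "hd_init", "count"),
    ("Peritoneal dialysis", "pd_init", "count"),
    ("Kidney transplantation", "tx_init", "count"),
    ("KRT costs (million EUR)", "cost_krt", "cost"),
    ("CVD complication costs (million EUR)", "cost_cvd", "cost"),
    ("Total costs (million EUR)", "cost_total", "cost"),
    ("QALY gain", "qalys", "qaly_gain"),
    ("NMB (million EUR)", None, "nmb"),
]


def _report_calendar_labels(start_year: int, horizon: int) -> dict[int, int]:
    """Report columns at model years 1 / 6 / 10, labelled start, +5, +10."""
    labels = {}
    for idx in REPORT_YEAR_INDICES:
        if idx > horizon:
            continue
        labels[idx] = start_year + (0 if idx == 1 else (5 if idx == 6 else 10))
    return labels


def build_accumulated_report(
    results: dict[float, ScenarioResult],
    reference_uptake: float = 0.15,
) -> pd.DataFrame:
    """Accumulated outcome table: one row per outcome, one column per
    (report year, uptake).  Counts are represented persons rounded at this
    layer only; costs in million EUR; QALY gain and NMB are vs the
    reference uptake scenario."""
    ref = results[reference_uptake]
    cfg = ref.config
    labels = _report_calendar_labels(cfg.start_year, cfg.horizon_years)
    cols: dict[tuple[int, float], dict[str, float]] = {}
    for uptake, res in sorted(results.items()):
        out = res.outcomes
        for idx, cal in labels.items():
            upto = out[out["year"] <= idx]
            ref_upto = ref.outcomes[ref.outcomes["year"] <= idx]
            col: dict[str, float] = {}
            for label, column, kind in TABLE_ROWS:
                if kind == "level":
                    col[label] = round(float(res.ledger.iloc[idx - 1]["eligible"]))
                elif kind == "count":
                    col[label] = round(float(upto[column].sum()))
                elif kind == "cost":
                    col[label] = round(float(upto[column].sum()) / 1e6, 1)
                elif kind == "qaly_gain":
                    col[label] = round(float(upto["qalys"].sum() - ref_upto["qalys"].sum()))
                elif kind == "nmb":
                    dq = float(upto["qalys"].sum() - ref_upto["qalys"].sum())
                    dc = float(upto["cost_total"].sum() - ref_upto["cost_total"].sum())
                    col[label] = round((cfg.lam * dq - dc) / 1e6, 1)
            cols[(cal, uptake)] = col
    frame = pd.DataFrame(cols)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["year", "uptake"])
    frame.index.name = "outcome"
    return frame


def run_base_case(
    bundle: ParameterBundle,
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    uptakes: tuple[float, ...] = BASE_UPTAKES,
) -> tuple[dict[float, ScenarioResult], pd.DataFrame]:
    """Three-scenario base case plus the accumulated report table."""
    results = run_uptake_scenarios(config, bundle, uptakes)
    report = build_accumulated_report(results, reference_uptake=min(uptakes))
    if out_dir is not None:
        write_outputs(results, report, bundle, Path(out_dir))
    return results, report


class SensitivityPreset(BaseModel):
    """Named bundle of scenario-config overrides; presets are composable."""

    name: str
    overrides: dict[str, float]

    _RANGES = {
        "annual_incidence": (17_600, 40_000),
        "mortality_target": (0.0, 1.0),
        "eligibility_fraction": (0.0, 1.0),
        "effect_scale": (0.0, 1.0),
        "price_multiplier": (0.0, 10.0),
    }

    @field_validator("overrides")
    @classmethod
    def _known_fields(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(ScenarioConfig.model_fields)
        if unknown:
            raise ValueError(f"overrides target unknown config fields {sorted(unknown)}")
        return v

    def apply(self, config: ScenarioConfig) -> ScenarioConfig:
        for field, value in self.overrides.items():
            rng = self._RANGES.get(field)
            if rng and not rng[0] <= value <= rng[1]:
                warnings.warn(
                    f"preset {self.name!r}: {field}={value} outside the studied "
                    f"range {rng}", stacklevel=2,
                )
        return config.model_copy(update=self.overrides)


STANDARD_PRESETS = {
    "incidence_low": SensitivityPreset(name="incidence_low",
                                       overrides={"annual_incidence": 17_600}),
    "incidence_high": SensitivityPreset(name="incidence_high",
                                        overrides={"annual_incidence": 40_000}),
    "mortality_57": SensitivityPreset(name="mortality_57",
                                      overrides={"mortality_target": 0.57}),
    "eligible_plus25": SensitivityPreset(
        name="eligible_plus25", overrides={"eligibility_fraction": 0.2675 * 1.25}
    ),
    "effect_80": SensitivityPreset(name="effect_80", overrides={"effect_scale": 0.8}),
    "price_20": SensitivityPreset(name="price_20", overrides={"price_multiplier": 0.2}),
}


def run_sensitivity(
    preset: SensitivityPreset,
    bundle: ParameterBundle,
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    uptakes: tuple[float, ...] = BASE_UPTAKES,
) -> tuple[dict[float, ScenarioResult], pd.DataFrame]:
    """Base case under a sensitivity preset.

    A ``mortality_target`` override re-runs the mortality calibration on the
    frozen cohort and substitutes the recovered multiplier before
    simulating.
    """
    cfg = preset.apply(config)
    if cfg.mortality_target is not None:
        cal = calibrate_mortality(cfg.mortality_target, bundle, seed=cfg.seed,
                                  uptake=min(uptakes))
        surface = bundle.mortality.model_copy(
            update={"calibration_multiplier": cal.multiplier}
        )
        bundle = bundle.model_copy(update={"mortality": surface})
    results = run_uptake_scenarios(cfg, bundle, uptakes)
    report = build_accumulated_report(results, reference_uptake=min(uptakes))
    if out_dir is not None:
        write_outputs(results, report, bundle, Path(out_dir), preset=preset)
    return results, report


def krt_capacity_report(
    scenario: ScenarioResult,
    capacity_band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-year prevalent KRT occupancy with below/within/above-band flags.

    Occupancy adds the configured share of the current national KRT
    population (patients who would have been treatment-eligible before
    initiating KRT) to the simulated prevalent KRT count.
    """
    cfg = scenario.config
    lo, hi = capacity_band if capacity_band is not None else cfg.krt_capacity_band
    out = scenario.outcomes
    occupancy = (
        out[["hd_prevalent", "pd_prevalent", "tx_prevalent"]].sum(axis=1)
        + cfg.krt_baseline_eligible_share * cfg.current_krt_patients
    )
    return pd.DataFrame(
        {
            "year": out["year"].astype(int),
            "calendar_year": out["calendar_year"].astype(int),
            "krt_prevalent": occupancy.round(0),
            "capacity_flag": capacity_flags(occupancy.to_numpy(), lo, hi),
        }
    )


def capacity_flags(occupancy, lo: float, hi: float):
    """below/within/above flags; an infinite band never flags 'above'."""
    occ = np.asarray(occupancy, dtype=float)
    return np.where(occ < lo, "below", np.where(occ <= hi, "within", "above"))


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record: same hash + seed implies identical outputs."""

    config_hash: str
    seed: int
    fixture_version: str
    created_at: str
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def build_manifest(
    bundle: ParameterBundle, config: ScenarioConfig, outputs: dict[str, str]
) -> RunManifest:
    scenario_payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    combined = hashlib.sha256(
        (bundle.config_hash() + scenario_payload).encode()
    ).hexdigest()[:16]
    return RunManifest(
        config_hash=combined,
        seed=config.seed,
        fixture_version=bundle.version,
        created_at=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=outputs,
    )


def write_outputs(
    results: dict[float, ScenarioResult],
    report: pd.DataFrame,
    bundle: ParameterBundle,
    out_dir: Path,
    preset: SensitivityPreset | None = None,
) -> RunManifest:
    """Write per-year CSVs, the accumulated report and a JSON manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    for uptake, res in sorted(results.items()):
        tag = f"uptake_{int(round(uptake * 100))}"
        per_year = out_dir / f"per_year_{tag}.csv"
        res.outcomes.to_csv(per_year, index=False)
        outputs[f"per_year_{tag}"] = per_year.name
        ledger_path = out_dir / f"ledger_{tag}.csv"
        res.ledger.to_csv(ledger_path, index=False)
        outputs[f"ledger_{tag}"] = ledger_path.name
    report_path = out_dir / "accumulated_report.csv"
    report.to_csv(report_path)
    outputs["accumulated_report"] = report_path.name
    any_cfg = results[min(results)].config
    manifest = build_manifest(bundle, any_cfg, outputs)
    payload = dataclasses.asdict(manifest)
    if preset is not None:
        payload["sensitivity_preset"] = preset.model_dump()
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return manifest
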