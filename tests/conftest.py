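import numpy as np
import pytest

import ckdsim as ck


@pytest.fixture(scope="session")
def bundle() -> ck.ParameterBundle:
    """The shipped frozen parameter fixture."""
    return ck.load_parameters()


@pytest.fixture(scope="session")
def null_hazard_bundle(bundle: ck.ParameterBundle) -> ck.ParameterBundle:
    """Bundle with mortality, complications and KRT initiation switched off."""
    surface = bundle.mortality.model_copy(update={"calibration_multiplier": 1e-12})
    models = {
        name: m.model_copy(update={"intercept": -30.0})
        for name, m in bundle.events.models.items()
    }
    events = bundle.events.model_copy(update={"models": models})
    krt = bundle.krt.model_copy(update={"initiation_probability": 0.0})
    return bundle.model_copy(update={"mortality": surface, "events": events, "krt": krt})


@pytest.fixture(scope="session")
def frozen_progression(bundle: ck.ParameterBundle) -> ck.ProgressionParameters:
    """Progression with all stochastic and drift terms disabled."""
    mods = bundle.progression.slope_modifiers.model_copy(
        update={
            "age_per_decade": 0.0, "diabetes": 0.0, "hypertension": 0.0,
            "sbp_per_10mmhg": 0.0, "hba1c_per_unit": 0.0,
            "uacr_a2": 0.0, "uacr_a3": 0.0,
        }
    )
    return bundle.progression.model_copy(
        update={
            "baseline_egfr_slope": -2.0, "slope_sd": 0.0, "slope_modifiers": mods,
            "uacr_annual_growth": 0.0, "sbp_annual_drift": 0.0,
            "hba1c_annual_drift": 0.0,
        }
    )


@pytest.fixture
def example_profile() -> ck.PatientProfile:
    """A typical prevalent patient at the published cohort means."""
    return ck.PatientProfile(
        id=0, age=76.0, male=False, egfr=56.0, uacr=75.0, hba1c=5.9, bmi=28.5,
        cholesterol=174.0, sbp=132.0, has_diabetes=False, has_cvd=False,
        has_hypertension=False, has_chf=False, on_sglt2i=False,
        state=ck.classify_state(56.0, 75.0), entry_year=1,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
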