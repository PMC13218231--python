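"""Parameter bundle: validated model configuration with a frozen fixture.

The package ships a versioned default parameter file
(``ckdsim/data/default_parameters.yaml``) holding the full model
parameterisation: cohort marginals, progression coefficients, treatment
effect, mortality surface, event-rate models, KRT transitions, costs and
utilities.  :func:`load_parameters` reads either that fixture or a
user-supplied YAML/JSON file of the same shape.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .cohort import CohortSpec
from .economics import CostSchedule, UtilitySchedule
from .events import EventRates, KrtTransitionMatrix, MortalitySurface
from .progression import ProgressionParameters, TreatmentEffect


class ParameterBundle(BaseModel):
    """Everything the simulation needs besides the scenario definition."""

    version: str = "unversioned"
    prevalent_cohort: CohortSpec
    incident_cohort: CohortSpec
    progression: ProgressionParameters = Field(default_factory=ProgressionParameters)
    treatment: TreatmentEffect = Field(default_factory=TreatmentEffect)
    mortality: MortalitySurface
    events: EventRates
    krt: KrtTransitionMatrix
    costs: CostSchedule
    utilities: UtilitySchedule

    def config_hash(self) -> str:
        """Stable content hash of the bundle (for run manifests)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_raw(path: str | Path | None) -> dict:
    if path is None:
        text = resources.files("ckdsim.data").joinpath("default_parameters.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def load_parameters(path: str | Path | None = None) -> ParameterBundle:
    """Load a :class:`ParameterBundle` (default: the shipped frozen fixture)."""
    raw = _read_raw(path)
    return ParameterBundle(**{k: v for k, v in raw.items() if k != "scenario"})


def load_scenario_defaults(path: str | Path | None = None) -> dict:
    """The ``scenario`` section of a parameter file, as a plain dict."""
    return dict(_read_raw(path).get("scenario", {}))


def save_parameters(bundle: ParameterBundle, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(bundle.model_dump(mode="json"), sort_keys=False))
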