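"""YAML configuration round-trip for parameters, scenario and meal profile."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .diurnal import MealProfileParams
from .kinetics import KineticParameters
from .scenarios import Scenario, baseline_scenario


class Config(BaseModel):
    """Top-level run configuration; zero-config defaults reproduce the
    published fold-change grid."""

    model_config = {"frozen": True}

    params: KineticParameters = Field(default_factory=KineticParameters)
    scenario: Scenario = Field(default_factory=baseline_scenario)
    meal_profile: MealProfileParams = Field(default_factory=MealProfileParams)

    def resolved_scenario(self) -> Scenario:
        """The scenario with the top-level kinetic parameters applied."""
        return self.scenario.model_copy(update={"params": self.params})


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )


def load_config(path: str | Path) -> Config:
    return Config.model_validate(yaml.safe_load(Path(path).read_text()))
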