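"""Parameter sweeps and local log-log sensitivities (elasticities)."""

from __future__ import annotations

import logging
import math

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .kinetics import KineticParameters
from .scenarios import Scenario, baseline_scenario, fold_change, scenario_activity

logger = logging.getLogger(__name__)

#: sweepable paths that live on the scenario rather than the parameters
_SCENARIO_PATHS = ("plasma_glucose", "gkrp_expression_multiplier")


class SweepSpec(BaseModel):
    """One-dimensional parameter sweep over a scenario."""

    model_config = {"frozen": True}

    parameter_path: str
    values: tuple[float, ...] | None = None
    start: float | None = None
    stop: float | None = None
    steps: int | None = None
    scenario: Scenario

    @model_validator(mode="after")
    def _resolve(self):
        if self.values is None:
            if None in (self.start, self.stop, self.steps):
                raise ValueError("provide either values or (start, stop, steps)")
            if self.steps < 2:
                raise ValueError("a sweep needs at least 2 points")
        elif len(self.values) < 2:
            raise ValueError("a sweep needs at least 2 points")
        return self

    def grid(self) -> list[float]:
        if self.values is not None:
            return list(self.values)
        step = (self.stop - self.start) / (self.steps - 1)
        return [self.start + i * step for i in range(self.steps)]


def _apply(scenario: Scenario, path: str, value: float) -> Scenario:
    """Return a scenario with one numeric field replaced."""
    if path in _SCENARIO_PATHS:
        return scenario.model_copy(update={path: value})
    if path in KineticParameters.model_fields:
        params = scenario.params.model_copy(update={path: value})
        return scenario.model_copy(update={"params": params})
    raise KeyError(f"parameter path {path!r} does not resolve to a numeric field")


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Fold change vs the fixed fasting baseline at each sweep point.

    The baseline keeps the scenario's unperturbed parameters throughout,
    so a sweep answers "what if this quantity deviated from its reference
    value" — e.g. raising gkrp_total monotonically lowers the fold change.
    """
    base = baseline_scenario(spec.scenario.params)
    rows = []
    for value in spec.grid():
        scen = _apply(spec.scenario, spec.parameter_path, value)
        result = fold_change(scen, base)
        rows.append(
            {
                spec.parameter_path: value,
                "fold_change": result.fold_change,
                "absolute_activity": result.absolute_activity,
            }
        )
    return pd.DataFrame(rows)


class ElasticityRecord(BaseModel):
    """d ln(output) / d ln(parameter) by central finite difference."""

    model_config = {"frozen": True}

    parameter_path: str
    base_value: float
    elasticity: float


def elasticities(
    scenario: Scenario,
    rel_step: float = 0.01,
    on: str = "fold_change",
    include_atp_term: bool = False,
) -> list[ElasticityRecord]:
    """Local elasticity of every kinetic parameter at a scenario.

    ``on`` selects the output: "fold_change" (normalized to the fasting
    baseline, where kcat_rel and the ATP factor cancel exactly) or
    "absolute" activity.  Parameters at zero are skipped with a warning.
    """
    if not 0 < rel_step < 0.1:
        raise ValueError("rel_step must lie in (0, 0.1)")
    if on not in ("fold_change", "absolute"):
        raise ValueError("on must be 'fold_change' or 'absolute'")

    def output(scen: Scenario) -> float:
        if on == "absolute":
            return scenario_activity(scen, include_atp_term)[0]
        base = baseline_scenario(scen.params)
        return fold_change(scen, base, include_atp_term).fold_change

    records = []
    for name in KineticParameters.model_fields:
        base_value = getattr(scenario.params, name)
        if base_value == 0:
            logger.warning("skipping %s: parameter is zero", name)
            continue
        hi = output(_apply(scenario, name, base_value * (1 + rel_step)))
        lo = output(_apply(scenario, name, base_value * (1 - rel_step)))
        d_ln_p = math.log1p(rel_step) - math.log1p(-rel_step)
        elasticity = (math.log(hi) - math.log(lo)) / d_ln_p
        records.append(
            ElasticityRecord(parameter_path=name, base_value=base_value, elasticity=elasticity)
        )
    return records
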