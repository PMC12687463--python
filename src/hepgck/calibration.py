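"""Rate-law form selection against the published fold-change grid.

The printed rate law is typographically ambiguous about where the
competitive-inhibition factor f = 1 + [GKRP]/Ki sits relative to the Hill
exponent, and about whether compartmentation matters.  This module makes
the choice empirical: every candidate algebra is evaluated against the
published wildtype, R227Ter and GKRP-overexpression fold changes with the
default parameters, and exactly one candidate — the two-compartment model
with denominator (S0.5 * f)^n + S^n — reproduces them within 0.05.

The P446L cells are excluded from the reference set: they are not
reproduced by any documented assumption combination (see docs/methods.md)
and would contaminate the selection.
"""

from __future__ import annotations

import enum
import json

from pydantic import BaseModel, Field

from .kinetics import (
    DenominatorForm,
    GKRPSpecies,
    KineticParameters,
    hill_rate,
    inhibition_factor,
)
from .scenarios import (
    Effector,
    TABLE1_CELLS,
    baseline_scenario,
    fold_change,
    scenario_for_cell,
)


class CompartmentScheme(str, enum.Enum):
    TWO_COMPARTMENT = "two_compartment_volume_weighted"
    SINGLE_POOL = "single_pool"


class RateLawCandidate(BaseModel):
    """One interpretation of the rate-law algebra."""

    model_config = {"frozen": True}

    label: str
    denominator_form: DenominatorForm
    compartment_scheme: CompartmentScheme


class DeviationReport(BaseModel):
    """Per-cell |model - printed| deviations for one candidate."""

    model_config = {"frozen": True}

    candidate: RateLawCandidate
    per_cell_deviation: dict[str, float]
    max_deviation: float

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2)


class CalibrationError(RuntimeError):
    """No candidate reproduced the reference cells within tolerance."""

    def __init__(self, reports: list[DeviationReport], tolerance: float):
        self.reports = reports
        self.tolerance = tolerance
        lines = ", ".join(
            f"{r.candidate.label}: {r.max_deviation:.3f}" for r in reports
        )
        super().__init__(
            f"no rate-law candidate within tolerance {tolerance}; "
            f"max deviations: {lines}"
        )


def default_candidates() -> list[RateLawCandidate]:
    """The shipped candidate set: 3 denominator forms x 2 schemes."""
    return [
        RateLawCandidate(
            label=f"{form.value}/{scheme.value}",
            denominator_form=form,
            compartment_scheme=scheme,
        )
        for form in DenominatorForm
        for scheme in CompartmentScheme
    ]


def reference_cells(
    include_variants: bool = True,
) -> list[tuple[float, str, Effector, float]]:
    """Published cells used for calibration (P446L rows excluded)."""
    cells = [c for c in TABLE1_CELLS if c[1] != "P446L_het"]
    if not include_variants:
        cells = [c for c in cells if c[1] == "wildtype"]
    return cells


def _single_pool_fold(
    glucose_mm: float,
    gkrp_species: list[GKRPSpecies],
    params: KineticParameters,
    form: DenominatorForm,
) -> float:
    """Cell-mean concentrations in one well-mixed pool (no partitioning)."""
    s = glucose_mm * params.hep_plasma_glucose_ratio
    return hill_rate(s, params.gck_total, inhibition_factor(gkrp_species), params, form=form)


def evaluate_candidate(
    candidate: RateLawCandidate,
    cells: list[tuple[float, str, Effector, float]] | None = None,
    params: KineticParameters | None = None,
) -> DeviationReport:
    """Deviation of one candidate's fold changes from the printed cells."""
    if cells is None:
        cells = reference_cells()
    params = params or KineticParameters()
    deviations: dict[str, float] = {}
    if candidate.compartment_scheme is CompartmentScheme.TWO_COMPARTMENT:
        base = baseline_scenario(params)
        for glucose, variant, effector, printed in cells:
            scen = scenario_for_cell(glucose, variant, effector, params)
            model = fold_change(scen, base, form=candidate.denominator_form).fold_change
            deviations[f"{glucose}mM/{variant}/{effector.value}"] = abs(model - printed)
    else:
        from .scenarios import build_allele_pool, Genotype

        def pool_for(variant: str, effector: Effector) -> list[GKRPSpecies]:
            if variant == "GKRPx2":
                return build_allele_pool(Genotype.WILDTYPE, effector, 2.0, params)
            return build_allele_pool(Genotype(variant), effector, 1.0, params)

        ref = _single_pool_fold(
            4.5, pool_for("wildtype", Effector.F6P_200UM), params, candidate.denominator_form
        )
        for glucose, variant, effector, printed in cells:
            model = (
                _single_pool_fold(
                    glucose, pool_for(variant, effector), params, candidate.denominator_form
                )
                / ref
            )
            deviations[f"{glucose}mM/{variant}/{effector.value}"] = abs(model - printed)
    max_dev = max(deviations.values(), default=0.0)
    return DeviationReport(
        candidate=candidate, per_cell_deviation=deviations, max_deviation=max_dev
    )


def select_rate_law_form(
    candidates: list[RateLawCandidate],
    cells: list[tuple[float, str, Effector, float]] | None = None,
    tolerance: float = 0.05,
    params: KineticParameters | None = None,
) -> RateLawCandidate:
    """Pick the candidate reproducing the reference cells within tolerance.

    Deterministic and order-independent: candidates are ranked by
    max deviation (label as tie-break) and the best within tolerance is
    returned.  Raises :class:`CalibrationError` if none qualifies.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    reports = [evaluate_candidate(c, cells, params) for c in candidates]
    reports.sort(key=lambda r: (r.max_deviation, r.candidate.label))
    if reports[0].max_deviation <= tolerance:
        return reports[0].candidate
    raise CalibrationError(reports, tolerance)


def calibration_report(
    tolerance: float = 0.05, params: KineticParameters | None = None
) -> dict:
    """Full JSON-serializable report over the shipped candidate set."""
    reports = [
        evaluate_candidate(c, params=params) for c in default_candidates()
    ]
    selected = select_rate_law_form(default_candidates(), tolerance=tolerance, params=params)
    return {
        "tolerance": tolerance,
        "selected": selected.model_dump(mode="json"),
        "reports": [r.model_dump(mode="json") for r in reports],
    }
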