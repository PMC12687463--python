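"""Diet/genotype scenarios and fold-change normalization.

A scenario fixes plasma glucose, the GKRP effector state (F6P or F1P at
their reference concentrations, or none), the GKRP genotype or expression
level, and the kinetic parameters.  Activities are reported as fold
changes relative to the fasting reference: wildtype, 4.5 mM plasma
glucose, 200 uM F6P.

Genotypes
---------
wildtype      one GKRP species at the full cellular concentration.
R227Ter het   premature-stop allele; modeled as 50% loss of functional
              GKRP (18 nM instead of 36 nM).
P446L het     missense allele expressed at normal level but with the F6P
              potentiation of GKRP binding lost; modeled as two 18 nM
              species, the mutant allele keeping the effector-free Ki
              (984 nM) under F6P while responding normally to F1P.
"""

from __future__ import annotations

import enum

import pandas as pd
from pydantic import BaseModel, Field

from .kinetics import (
    CompartmentState,
    Compartment,
    DenominatorForm,
    GKRPSpecies,
    KineticParameters,
    cell_mean_activity,
    partition_compartments,
)

#: plasma glucose at/below which fasting nucleus/cytosol ratios apply (mM)
FASTING_GLUCOSE_MM = 4.5
#: plasma glucose at/above which fed-state ratios apply (mM)
FED_GLUCOSE_MM = 7.0


class Effector(str, enum.Enum):
    F6P_200UM = "F6P_200uM"
    F1P_100UM = "F1P_100uM"
    NONE = "none"


class Genotype(str, enum.Enum):
    WILDTYPE = "wildtype"
    P446L_HET = "P446L_het"
    R227TER_HET = "R227Ter_het"


class Scenario(BaseModel):
    """One model evaluation point."""

    model_config = {"frozen": True}

    plasma_glucose: float = Field(gt=0, description="mM")
    effector: Effector = Effector.F6P_200UM
    genotype: Genotype = Genotype.WILDTYPE
    gkrp_expression_multiplier: float = Field(default=1.0, gt=0)
    ki_p446l: float | None = Field(
        default=None,
        gt=0,
        description=(
            "Ki of the P446L allele under F6P (nM); None means full loss "
            "of F6P potentiation, i.e. ki_base"
        ),
    )
    params: KineticParameters = Field(default_factory=KineticParameters)


class ActivityResult(BaseModel):
    """Activity of a scenario, normalized to a baseline scenario."""

    model_config = {"frozen": True}

    scenario: Scenario
    absolute_activity: float = Field(gt=0, description="relative units")
    fold_change: float = Field(gt=0)
    compartment_breakdown: dict[str, float]


def baseline_scenario(params: KineticParameters | None = None) -> Scenario:
    """The normalization reference: wildtype, 4.5 mM glucose, 200 uM F6P."""
    return Scenario(
        plasma_glucose=FASTING_GLUCOSE_MM,
        effector=Effector.F6P_200UM,
        genotype=Genotype.WILDTYPE,
        params=params or KineticParameters(),
    )


def _effector_ki(effector: Effector, params: KineticParameters) -> float:
    return {
        Effector.F6P_200UM: params.ki_f6p,
        Effector.F1P_100UM: params.ki_f1p,
        Effector.NONE: params.ki_base,
    }[effector]


def build_allele_pool(
    genotype: Genotype,
    effector: Effector,
    multiplier: float,
    params: KineticParameters,
    ki_p446l: float | None = None,
) -> list[GKRPSpecies]:
    """Cell-mean GKRP species implied by a genotype/effector combination.

    P446L responds normally to F1P (binding is lifted as in wildtype) but
    has lost the F6P potentiation, so under F6P — and trivially with no
    effector — the mutant allele sits at the effector-free Ki unless a
    different ``ki_p446l`` is supplied.
    """
    if multiplier <= 0:
        raise ValueError("expression multiplier must be > 0")
    ki_wt = _effector_ki(effector, params)
    total = params.gkrp_total * multiplier
    if genotype is Genotype.WILDTYPE:
        return [GKRPSpecies(label="wt", concentration=total, ki=ki_wt)]
    if genotype is Genotype.R227TER_HET:
        return [GKRPSpecies(label="wt", concentration=0.5 * total, ki=ki_wt)]
    if genotype is Genotype.P446L_HET:
        if effector is Effector.F1P_100UM:
            ki_mut = params.ki_f1p
        else:
            ki_mut = ki_p446l if ki_p446l is not None else params.ki_base
        return [
            GKRPSpecies(label="wt", concentration=0.5 * total, ki=ki_wt),
            GKRPSpecies(label="P446L", concentration=0.5 * total, ki=ki_mut),
        ]
    raise ValueError(f"unknown genotype: {genotype}")


def resolve_compartment_ratios(
    plasma_glucose: float, params: KineticParameters
) -> tuple[float, float]:
    """Nucleus/cytosol ratios (GCK, GKRP) at a given plasma glucose.

    Translocation is reported at two states only — fasting (<= 4.5 mM,
    both ratios 3.5) and fed (>= 7.0 mM, ratios 2.0 and 3.0); between
    them the ratios are linearly interpolated for continuity.
    """
    if plasma_glucose <= 0:
        raise ValueError("plasma glucose must be > 0")
    if plasma_glucose <= FASTING_GLUCOSE_MM:
        return params.nc_ratio_fasting, params.nc_ratio_fasting
    if plasma_glucose >= FED_GLUCOSE_MM:
        return params.nc_ratio_gck_fed, params.nc_ratio_gkrp_fed
    t = (plasma_glucose - FASTING_GLUCOSE_MM) / (FED_GLUCOSE_MM - FASTING_GLUCOSE_MM)
    gck = params.nc_ratio_fasting + t * (params.nc_ratio_gck_fed - params.nc_ratio_fasting)
    gkrp = params.nc_ratio_fasting + t * (params.nc_ratio_gkrp_fed - params.nc_ratio_fasting)
    return gck, gkrp


def build_compartments(scenario: Scenario) -> list[CompartmentState]:
    """Translate a scenario into nucleus + cytosol compartment states."""
    params = scenario.params
    glucose = scenario.plasma_glucose * params.hep_plasma_glucose_ratio
    r_gck, r_gkrp = resolve_compartment_ratios(scenario.plasma_glucose, params)
    gck_n, gck_c = partition_compartments(params.gck_total, r_gck)
    pool = build_allele_pool(
        scenario.genotype,
        scenario.effector,
        scenario.gkrp_expression_multiplier,
        params,
        scenario.ki_p446l,
    )
    pool_n, pool_c = [], []
    for sp in pool:
        c_n, c_c = partition_compartments(sp.concentration, r_gkrp)
        pool_n.append(GKRPSpecies(label=sp.label, concentration=c_n, ki=sp.ki))
        pool_c.append(GKRPSpecies(label=sp.label, concentration=c_c, ki=sp.ki))
    return [
        CompartmentState(
            compartment=Compartment.NUCLEUS,
            gck=gck_n,
            gkrp_pool=pool_n,
            glucose=glucose,
            volume_fraction=0.5,
        ),
        CompartmentState(
            compartment=Compartment.CYTOSOL,
            gck=gck_c,
            gkrp_pool=pool_c,
            glucose=glucose,
            volume_fraction=0.5,
        ),
    ]


def scenario_activity(
    scenario: Scenario,
    include_atp_term: bool = False,
    form: DenominatorForm = DenominatorForm.SCALED_S_HALF,
) -> tuple[float, dict[str, float]]:
    """Cell-mean activity of a scenario plus the per-compartment rates."""
    compartments = build_compartments(scenario)
    breakdown = {
        comp.compartment.value: cell_mean_activity(
            [comp.model_copy(update={"volume_fraction": 1.0})],
            scenario.params,
            include_atp_term,
            form,
        )
        for comp in compartments
    }
    activity = cell_mean_activity(compartments, scenario.params, include_atp_term, form)
    return activity, breakdown


def fold_change(
    scenario: Scenario,
    baseline: Scenario | None = None,
    include_atp_term: bool = False,
    form: DenominatorForm = DenominatorForm.SCALED_S_HALF,
) -> ActivityResult:
    """Activity of ``scenario`` normalized to ``baseline`` (fasting wildtype).

    The baseline scenario shares the kinetic parameters of ``scenario``
    unless given explicitly; a scenario normalized against itself yields
    a fold change of exactly 1.
    """
    if baseline is None:
        baseline = baseline_scenario(scenario.params)
    activity, breakdown = scenario_activity(scenario, include_atp_term, form)
    ref_activity, _ = scenario_activity(baseline, include_atp_term, form)
    if ref_activity <= 0:
        raise ArithmeticError("baseline activity is zero; cannot normalize")
    return ActivityResult(
        scenario=scenario,
        absolute_activity=activity,
        fold_change=activity / ref_activity,
        compartment_breakdown=breakdown,
    )


# Printed reference grid: (plasma glucose mM, variant label, effector,
# published fold change).  The P446L rows are retained for reporting but
# are known not to be reproduced by the default assumptions (see
# docs/methods.md).
TABLE1_CELLS: list[tuple[float, str, Effector, float]] = [
    (4.5, "wildtype", Effector.F6P_200UM, 1.0),
    (7.0, "wildtype", Effector.F6P_200UM, 1.9),
    (9.0, "wildtype", Effector.F6P_200UM, 2.4),
    (11.0, "wildtype", Effector.F6P_200UM, 2.9),
    (7.0, "wildtype", Effector.F1P_100UM, 3.4),
    (9.0, "wildtype", Effector.F1P_100UM, 4.0),
    (11.0, "wildtype", Effector.F1P_100UM, 4.4),
    (4.5, "P446L_het", Effector.F6P_200UM, 1.6),
    (11.0, "P446L_het", Effector.F6P_200UM, 3.6),
    (11.0, "P446L_het", Effector.F1P_100UM, 4.4),
    (4.5, "R227Ter_het", Effector.F6P_200UM, 1.4),
    (11.0, "R227Ter_het", Effector.F6P_200UM, 3.6),
    (11.0, "R227Ter_het", Effector.F1P_100UM, 4.4),
    (7.0, "GKRPx2", Effector.F6P_200UM, 1.2),
    (11.0, "GKRPx2", Effector.F6P_200UM, 2.1),
    (11.0, "GKRPx2", Effector.F1P_100UM, 4.4),
]


def scenario_for_cell(
    plasma_glucose: float,
    variant: str,
    effector: Effector,
    params: KineticParameters,
) -> Scenario:
    """Scenario matching one reference-grid cell label."""
    if variant == "GKRPx2":
        return Scenario(
            plasma_glucose=plasma_glucose,
            effector=effector,
            gkrp_expression_multiplier=2.0,
            params=params,
        )
    return Scenario(
        plasma_glucose=plasma_glucose,
        effector=effector,
        genotype=Genotype(variant) if variant != "wildtype" else Genotype.WILDTYPE,
        params=params,
    )


def reproduce_table1(
    params: KineticParameters | None = None, tolerance: float = 0.05
) -> pd.DataFrame:
    """Recompute the published fold-change grid and flag deviations.

    Returns a tidy frame with one row per populated cell: plasma glucose,
    variant, effector, model fold change (raw and rounded half-up to one
    decimal), the published value, the absolute pre-rounding deviation,
    and a flag for deviations beyond ``tolerance``.
    """
    params = params or KineticParameters()
    base = baseline_scenario(params)
    rows = []
    for glucose, variant, effector, printed in TABLE1_CELLS:
        result = fold_change(scenario_for_cell(glucose, variant, effector, params), base)
        deviation = abs(result.fold_change - printed)
        rows.append(
            {
                "plasma_glucose_mM": glucose,
                "variant": variant,
                "effector": effector.value,
                "fold_change": result.fold_change,
                "fold_change_rounded": round_half_up(result.fold_change),
                "printed": printed,
                "abs_deviation": deviation,
                "flagged": deviation > tolerance,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as the printed grid does."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))
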