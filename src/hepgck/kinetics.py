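"""Rate law for in situ glucokinase activity in a two-compartment hepatocyte.

Hepatic glucokinase (GCK) follows sigmoidal (Hill) kinetics in glucose and
is competitively inhibited by the glucokinase regulatory protein (GKRP).
The inhibitor enters the rate law by scaling the half-saturating glucose
concentration:

    r = kcat * [GCK] * S^n / ((S0.5 * f)^n + S^n),   f = 1 + sum_i [GKRP_i]/Ki_i

where S is hepatocyte glucose, S0.5 the half-saturation constant, n the
Hill coefficient, and the sum runs over co-existing GKRP species (e.g. the
two alleles of a heterozygote), each with its own inhibitory constant Ki.
Ki depends on the effector state: fructose-6-phosphate (F6P) tightens GKRP
binding (Ki = 45 nM at 200 uM F6P), fructose-1-phosphate (F1P) loosens it
(Ki = 7000 nM at saturating 100 uM F1P); without either, Ki = 984 nM.

Both nuclear and cytosolic GCK are catalytically active.  GCK and GKRP are
concentrated in the nucleus (nucleus/cytosol ratio ~3.5 when fasting,
relaxing to 2.0 for GCK and 3.0 for GKRP when fed); the cell-mean activity
is the volume-weighted mean of the compartment-local rates.  ATP saturates
GCK ([ATP] = 2 mM >> KM 0.4 mM), so the ATP factor is optional and cancels
from all fold changes.
"""

from __future__ import annotations

import enum
from typing import Sequence

from pydantic import BaseModel, Field, field_validator, model_validator


class DenominatorForm(str, enum.Enum):
    """Algebraic placement of the inhibition factor f in the denominator.

    The shipped model uses SCALED_S_HALF; the alternatives exist so the
    calibration module can demonstrate they fail to reproduce the
    reference fold changes.
    """

    SCALED_S_HALF = "scaled_s_half"          # (S0.5 * f)^n + S^n
    FACTOR_POWER = "factor_power"            # S0.5 * f^n + S^n
    LINEAR_FACTOR = "linear_factor"          # S0.5^n * f + S^n


class KineticParameters(BaseModel):
    """All rate-law constants, with units, defaulting to the printed values.

    Attributes
    ----------
    s_half : float
        Half-saturating glucose concentration of GCK, mM.
    hill_n : float
        Hill coefficient (cooperativity), dimensionless, >= 1.
    gck_total, gkrp_total : float
        Cell-mean concentrations of GCK and GKRP, nM.
    ki_base, ki_f6p, ki_f1p : float
        GKRP-GCK inhibitory constants (nM): no effector, +200 uM F6P,
        +100 uM F1P (saturating).
    km_atp, atp : float
        KM for ATP and hepatocyte ATP concentration, mM.
    nc_ratio_fasting : float
        Nucleus/cytosol concentration ratio of both GCK and GKRP at
        fasting glucose.
    nc_ratio_gck_fed, nc_ratio_gkrp_fed : float
        The same ratios in the fed state (GCK translocates more).
    hep_plasma_glucose_ratio : float
        Hepatocyte/plasma glucose concentration ratio.
    kcat_rel : float
        Relative turnover number; activities are reported in units of
        kcat_rel * nM, so fold changes are independent of it.
    """

    model_config = {"frozen": True}

    s_half: float = 7.6
    hill_n: float = 1.7
    gck_total: float = 27.0
    gkrp_total: float = 36.0
    ki_base: float = 984.0
    ki_f6p: float = 45.0
    ki_f1p: float = 7000.0
    km_atp: float = 0.4
    atp: float = 2.0
    nc_ratio_fasting: float = 3.5
    nc_ratio_gck_fed: float = 2.0
    nc_ratio_gkrp_fed: float = 3.0
    hep_plasma_glucose_ratio: float = 1.3
    kcat_rel: float = 1.0

    @field_validator("*")
    @classmethod
    def _strictly_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("all kinetic constants must be strictly positive")
        return v

    @field_validator("hill_n")
    @classmethod
    def _cooperative(cls, v: float) -> float:
        if v < 1:
            raise ValueError("hill_n must be >= 1")
        return v


class GKRPSpecies(BaseModel):
    """One GKRP population (e.g. an allele product) with its own Ki."""

    model_config = {"frozen": True}

    label: str
    concentration: float = Field(ge=0, description="nM, context-local")
    ki: float = Field(gt=0, description="nM")


class Compartment(str, enum.Enum):
    NUCLEUS = "nucleus"
    CYTOSOL = "cytosol"


class CompartmentState(BaseModel):
    """Local state of one compartment: enzyme, inhibitor pool, glucose."""

    model_config = {"frozen": True}

    compartment: Compartment
    gck: float = Field(ge=0, description="nM")
    gkrp_pool: tuple[GKRPSpecies, ...] = ()
    glucose: float = Field(ge=0, description="hepatocyte glucose, mM")
    volume_fraction: float = Field(gt=0, le=1)

    @model_validator(mode="before")
    @classmethod
    def _coerce_pool(cls, data):
        if isinstance(data, dict) and isinstance(data.get("gkrp_pool"), list):
            data = {**data, "gkrp_pool": tuple(data["gkrp_pool"])}
        return data


def partition_compartments(
    mean_conc: float, nc_ratio: float, volume_fraction_nucleus: float = 0.5
) -> tuple[float, float]:
    """Split a cell-mean concentration into nucleus/cytosol local values.

    Solves c_n / c_c = nc_ratio together with the volume-weighted mean
    v * c_n + (1 - v) * c_c = mean_conc.

    Returns
    -------
    (nucleus_conc, cytosol_conc) in the units of ``mean_conc``.
    """
    if mean_conc < 0:
        raise ValueError("mean_conc must be >= 0")
    if nc_ratio <= 0:
        raise ValueError("nc_ratio must be > 0")
    if not 0 < volume_fraction_nucleus < 1:
        raise ValueError("volume_fraction_nucleus must lie strictly in (0, 1)")
    v = volume_fraction_nucleus
    cytosol = mean_conc / (v * nc_ratio + (1 - v))
    return nc_ratio * cytosol, cytosol


def inhibition_factor(gkrp_pool: Sequence[GKRPSpecies]) -> float:
    """Competitive-inhibition factor f = 1 + sum_i [GKRP_i] / Ki_i.

    Species combine additively, the standard form for independent
    competitive inhibitors sharing a binding site; always >= 1.
    """
    total = 0.0
    for sp in gkrp_pool:
        if sp.ki <= 0:
            raise ValueError(f"species {sp.label!r} has non-positive Ki")
        if sp.concentration < 0:
            raise ValueError(f"species {sp.label!r} has negative concentration")
        total += sp.concentration / sp.ki
    return 1.0 + total


def _denominator(
    s_half: float, factor: float, glucose: float, n: float, form: DenominatorForm
) -> float:
    if form is DenominatorForm.SCALED_S_HALF:
        return (s_half * factor) ** n + glucose**n
    if form is DenominatorForm.FACTOR_POWER:
        return s_half * factor**n + glucose**n
    if form is DenominatorForm.LINEAR_FACTOR:
        return s_half**n * factor + glucose**n
    raise ValueError(f"unknown denominator form: {form}")


def hill_rate(
    glucose: float,
    gck: float,
    factor: float,
    params: KineticParameters,
    include_atp_term: bool = False,
    form: DenominatorForm = DenominatorForm.SCALED_S_HALF,
) -> float:
    """GCK rate (relative units, kcat_rel * nM) at local conditions.

    Parameters
    ----------
    glucose : hepatocyte glucose, mM.
    gck : local GCK concentration, nM.
    factor : competitive-inhibition factor, >= 1 (1 means no GKRP).
    include_atp_term : multiply by atp / (km_atp + atp); off by default
        because GCK is ATP-saturated and the term cancels in fold changes.
    """
    if glucose < 0:
        raise ValueError("glucose must be >= 0")
    if gck < 0:
        raise ValueError("gck must be >= 0")
    if factor < 1:
        raise ValueError("inhibition factor must be >= 1")
    if glucose == 0:
        rate = 0.0
    else:
        rate = (
            params.kcat_rel
            * gck
            * glucose**params.hill_n
            / _denominator(params.s_half, factor, glucose, params.hill_n, form)
        )
    if include_atp_term:
        rate *= params.atp / (params.km_atp + params.atp)
    return rate


def cell_mean_activity(
    compartments: Sequence[CompartmentState],
    params: KineticParameters,
    include_atp_term: bool = False,
    form: DenominatorForm = DenominatorForm.SCALED_S_HALF,
) -> float:
    """Volume-weighted mean of compartment-local GCK rates.

    The compartments must tile the cell (volume fractions sum to 1 within
    1e-9); each rate uses its compartment-local GCK, GKRP pool and glucose.
    """
    total_volume = sum(c.volume_fraction for c in compartments)
    if abs(total_volume - 1.0) > 1e-9:
        raise ValueError(
            f"compartment volume fractions must sum to 1, got {total_volume!r}"
        )
    activity = 0.0
    for comp in compartments:
        f = inhibition_factor(comp.gkrp_pool)
        activity += comp.volume_fraction * hill_rate(
            comp.glucose, comp.gck, f, params, include_atp_term, form
        )
    return activity
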