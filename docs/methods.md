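# Methods

## Model

The quantity modeled is the apparent *in situ* activity of glucokinase
(GCK) in a human hepatocyte, i.e. the GCK-catalyzed glucose → G6P rate
under the cell's own enzyme, inhibitor and substrate concentrations.
GCK follows a Hill rate law in glucose and is competitively inhibited by
the glucokinase regulatory protein (GKRP); competitive inhibition scales
the half-saturation constant:

    r = kcat · [GCK] · S^n / ((S0.5 · f)^n + S^n)
    f = 1 + Σ_i [GKRP_i] / Ki_i

The sum over GKRP species is the standard combination rule for
independent competitive inhibitors sharing a binding site; it is what
makes heterozygotes (two allele products with different Ki) expressible
without any extra mechanism.

The cell is two well-mixed compartments, nucleus and cytosol, of equal
volume. A nucleus/cytosol concentration ratio R partitions each
cell-mean concentration c̄ by solving c_n / c_c = R with
v·c_n + (1−v)·c_c = c̄. Both compartments see the same hepatocyte
glucose (1.3 × plasma glucose; glucose equilibrates rapidly across the
GLUT2-expressing membrane), each compartment's rate uses its local GCK
and GKRP, and the cell-mean activity is the volume-weighted mean of the
two rates. Glucose-driven translocation enters through the ratios: 3.5
for both proteins at fasting glucose (≤ 4.5 mM plasma), 2.0 (GCK) and
3.0 (GKRP) when fed (≥ 7.0 mM), linearly interpolated in between — the
interpolation is our choice for continuity; the reference grid never
queries that region, so no published value constrains it.

ATP is a saturated cofactor ([ATP] = 2 mM against K_M = 0.4 mM), so the
optional factor atp/(km_atp + atp) is a constant multiplier, off by
default and provably cancelling from every fold change (a property test
asserts this). kcat is unknown; with kcat_rel = 1 all activities are
relative and only fold changes against the fasting baseline (wildtype,
4.5 mM plasma glucose, 200 µM F6P) are reported — which is all the
reference grid reports.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| s_half | 7.6 | mM | GCK half-saturating glucose |
| hill_n | 1.7 | – | cooperativity |
| gck_total / gkrp_total | 27 / 36 | nM | cell-mean concentrations |
| ki_base | 984 | nM | GKRP Ki, no effector |
| ki_f6p | 45 | nM | GKRP Ki at 200 µM F6P (upper physiological limit) |
| ki_f1p | 7000 | nM | GKRP Ki at saturating (100 µM) F1P |
| km_atp / atp | 0.4 / 2 | mM | ATP saturation (optional term) |
| nc_ratio_fasting | 3.5 | – | nucleus/cytosol ratio, both proteins, fasting |
| nc_ratio_gck_fed / nc_ratio_gkrp_fed | 2.0 / 3.0 | – | fed-state ratios |
| hep_plasma_glucose_ratio | 1.3 | – | hepatocyte/plasma glucose |
| kcat_rel | 1 | – | relative turnover (normalization) |

All are literature-measured values except kcat_rel (a normalization) and
the interpolation rule above.

## Rate-law calibration

The published formula's typography leaves the exponent placement
ambiguous, and one could doubt whether compartmentation matters. Rather
than argue typography, the calibration module enumerates six candidate
algebras — denominator (S0.5·f)^n + S^n, S0.5·f^n + S^n, or
S0.5^n·f + S^n, each as a two-compartment or a single-pool model — and
scores each against the published wildtype, R227Ter and 2×GKRP fold
changes at default parameters. Exactly one candidate, the
two-compartment (S0.5·f)^n form, reproduces every reference cell within
0.05 pre-rounding; the single-pool variant of the same algebra misses
the 7 mM wildtype cell by ≈0.15, and the alternative exponent placements
by more. The selection is deterministic and order-independent, and the
shipped model hard-defaults to the winning form (the calibration is a
validation gate, not a runtime fit). P446L cells are excluded from the
reference set because they are not reproducible (below) and would
contaminate the selection.

## Variants and expression scenarios

- **Wildtype**: one species, 36 nM, effector-dependent Ki.
- **R227Ter heterozygote**: premature stop, no functional protein from
  one allele → one species at 18 nM.
- **P446L heterozygote**: both alleles expressed at normal level; the
  mutant protein binds and inhibits GCK normally and responds normally
  to F1P, but has lost F6P potentiation. Default: mutant allele at the
  effector-free Ki (984 nM) under F6P — i.e. complete loss of
  potentiation — configurable via `ki_p446l` since only "decreased" is
  documented, without a number.
- **GKRP over-expression** (ChREBP induction): wildtype species at
  multiplier × 36 nM.

F6P and F1P states are mutually exclusive alternatives, as in the
reference grid; no combined-effector state is modeled.

**Known limitation — P446L.** The published fasting fold change for the
P446L heterozygote is 1.6; the model gives 1.406 under the default
assumption, and no documented assumption combination we tried recovers
1.6 (fed-state translocation ratios at fasting glucose give ≈1.5; the
value may rest on an additional unstated assumption such as altered
nuclear retention of the variant). The 11 mM P446L cell is similarly
slightly off (model 3.535 vs printed 3.6, a 0.065 gap just over the
0.05 tolerance). Both cells are reported with their deviations and
flagged by `reproduce_table1`; the test suite asserts the model's own
values and the size of the gap rather than forcing agreement.

## Diurnal simulator

The synthetic-data stage emulates healthy-subject diurnal sugar
dynamics: fasting plasma fructose 20 µM rising at each meal to a peak
drawn uniformly from 300–600 µM (per-meal, seeded) and returning with a
30 min half-life; plasma glucose 5 mM rising to 7 mM at meals with the
same half-life. Excursions rise instantaneously and decay first-order —
the simplest shape consistent with the stated peak and half-life — and
overlapping meals sum. Default meals at 08:00, 13:00 and 19:00 on a
1-min grid (1441 points, well under a second to simulate).

Mapping fructose to the GKRP effector state: hepatocyte fructose is
plasma fructose divided by the steep uptake gradient (~30, hepatocytes
consume fructose avidly); ketohexokinase kinetics are fast (hepatic F1P
peaks within ~3 min and clears within ~10 min), so F1P-site occupancy
θ = F_hep/(F_hep + Kd) is treated as instantaneous in plasma fructose
(quasi-steady state). GKRP is then a two-state mixture — fraction θ at
the F1P-relieved Ki (7000 nM), 1−θ at the F6P-potentiated Ki (45 nM) —
which, because competitive factors add, behaves as a single species with
the harmonic-mean Ki: 1/Ki_eff = θ/ki_f1p + (1−θ)/ki_f6p. **The F1P-site
Kd default (10 µM hepatocyte-fructose equivalent) is a placeholder, not
a measured value**; no measured Kd or hepatocyte F1P time profile under
realistic meals is available, so absolute diurnal fold changes should be
read as scenario illustrations, not predictions. The ketohexokinase K_M
(800 µM fructose) is carried on the parameter set for rate-limited
variants but unused by default.

Instantaneous activity reuses the steady-state scenario machinery
(translocation ratios, partitioning, glucose gradient) with the
effective Ki substituted, so diurnal and steady-state results coincide
at matched concentrations (a cross-module test pins this). Exposure
metrics are trapezoidal: time-averaged fold change, AUC of (fold − 1)
in fold·min, and peak fold.

What the generator does *not* emulate: insulin/glucagon and incretin
regulation of the glucose excursion shape, inter-meal variability of
timing, intestinal fructose metabolism, glycogen buffering, and any
downstream glycolytic state. Passing tests therefore demonstrate the
model's internal consistency and its stated meal dynamics, not fidelity
to any individual's measured day.

## Sensitivity

`sweep` varies one numeric field (kinetic parameter, plasma glucose or
expression multiplier) against the fixed fasting baseline of the
unperturbed parameters. `elasticities` computes d ln(output)/d ln(p) by
central finite difference (default relative step 0.01, bounded to
(0, 0.1)); on fold changes the kcat_rel and ATP elasticities are exactly
zero (normalization cancellation), a useful self-check.

## Numerical choices

- Fold changes of a scenario against itself are exactly 1 (same float
  path, single division).
- Comparisons against published cells use half-up rounding to one
  decimal with a ±0.05 pre-rounding tolerance; `round_half_up` uses
  decimal arithmetic to avoid banker's rounding.
- Compartment volume fractions must sum to 1 within 1e-9.
- Zero glucose yields zero rate (the 0^n limit is taken explicitly).
- RNG: `numpy.random.default_rng(seed)` with spawned child streams for
  the glucose and fructose channels, so a matched fructose-free day has
  a bit-identical glucose channel at the same seed.

## Problem sizes

The reference grid is 16 scenario evaluations; calibration is 6 × 14
evaluations; a diurnal day is 1441 steps. The entire suite, including
the ~200-case-per-property randomized invariants, runs in a few seconds
on one CPU.
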