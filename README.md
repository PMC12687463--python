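# hepgck

A compartmental kinetic model of *in situ* glucokinase (GCK) activity in
human hepatocytes under control of the glucokinase regulatory protein
(GKRP), for researchers studying hepatic carbohydrate metabolism and the
"glycolytic overload" route to metabolic dysfunction-associated steatotic
liver disease (MASLD).

## The model

GCK catalyzes the rate-controlling first step of hepatic glucose
metabolism with sigmoidal kinetics, and is competitively inhibited by
GKRP. The inhibitor scales the half-saturation constant of a Hill rate
law:

```
r = kcat [GCK] S^n / ((S0.5 · f)^n + S^n),    f = 1 + Σᵢ [GKRPᵢ]/Ki,ᵢ
```

with hepatocyte glucose `S`, half-saturation `S0.5 = 7.6 mM`, Hill
coefficient `n = 1.7`, and an inhibition factor `f` summed over co-existing
GKRP species (the two alleles of a heterozygote, for instance). The GKRP
inhibitory constant depends on the effector state: fructose-6-phosphate
potentiates binding (Ki = 45 nM at 200 µM F6P), fructose-1-phosphate —
formed from dietary fructose by ketohexokinase — relieves it
(Ki = 7000 nM at saturating F1P); without either, Ki = 984 nM.

The cell is modeled as two equal-volume compartments. GCK and GKRP are
enriched in the nucleus (nucleus/cytosol ratio ≈ 3.5 when fasting,
relaxing to 2.0 for GCK and 3.0 for GKRP when fed); both nuclear and
cytosolic GCK are active, hepatocyte glucose is 1.3 × plasma glucose, and
the cell-mean activity is the volume-weighted mean of the two local
rates. Activities are reported as fold changes against the fasting
reference (wildtype, 4.5 mM plasma glucose, 200 µM F6P), so the unknown
kcat and the (saturated) ATP factor cancel.

On top of the rate law the package provides:

- **scenarios** — diet/genotype grids: F6P/F1P effector states, the GKRP
  variants P446L (heterozygous loss of F6P potentiation) and R227Ter
  (heterozygous null, 50% functional GKRP), and ChREBP-induced 2-fold
  GKRP over-expression;
- **calibration** — empirical selection of the rate-law algebra: six
  candidate interpretations (three denominator placements × two
  compartment schemes) are scored against the published fold-change grid
  and exactly one survives;
- **diurnal simulation** — synthetic 24-h plasma glucose/fructose
  profiles with realistic meal dynamics (fructose 20 µM fasting → 300–600
  µM peaks, ~30 min return half-life; glucose 5 → 7 mM), mapped through
  F1P-site occupancy to instantaneous GCK activity and integrated into
  overload exposure metrics;
- **sensitivity** — parameter sweeps and local elasticities
  (d ln activity / d ln parameter).

## Worked example

```python
>>> import hepgck as h
>>> table = h.reproduce_table1()
>>> print(table[["plasma_glucose_mM", "variant", "effector",
...              "fold_change_rounded", "printed"]].head(7).to_string(index=False))
 plasma_glucose_mM  variant  effector  fold_change_rounded  printed
               4.5 wildtype F6P_200uM                  1.0      1.0
               7.0 wildtype F6P_200uM                  1.9      1.9
               9.0 wildtype F6P_200uM                  2.4      2.4
              11.0 wildtype F6P_200uM                  2.9      2.9
               7.0 wildtype F1P_100uM                  3.4      3.4
               9.0 wildtype F1P_100uM                  4.0      4.0
              11.0 wildtype F1P_100uM                  4.4      4.4
```

Reading: raising plasma glucose from the fasting 4.5 mM to the absorptive
7–11 mM increases *in situ* GCK activity 1.9–2.9-fold; with saturating
F1P from concurrent dietary fructose, the same glucose excursion yields
3.4–4.4-fold — the quantitative core of the glycolytic-overload argument.

A simulated high-sugar day:

```python
>>> series = h.simulate_day(h.MealProfileParams(seed=1))
>>> h.integrate_exposure(series)
OverloadSummary(time_averaged_fold_change=1.112562542937342,
                auc_above_fasting=162.0900618297722,
                peak_fold_change=2.1731610583664023)
```

Three meals push instantaneous GCK activity to a 2.17-fold peak over the
fasting state and accumulate ≈162 fold·min of excess exposure over the
day.

The same functionality is exposed on the command line:

```sh
hepgck table1 --out table1.csv
hepgck diurnal --seed 1 --out day.csv --summary-out day.json
hepgck sweep --parameter plasma_glucose --start 4.5 --stop 11 --steps 14
hepgck calibrate
```

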