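# ckdsim

Dynamic patient-level microsimulation of chronic kidney disease (CKD)
progression in Denmark under alternative SGLT2 inhibitor (SGLT2i) uptake
scenarios, with a health-economics layer for budget-impact analysis.

The package is for health-economic modellers and nephrology researchers who
want to rerun, perturb or extend a national uptake analysis at desk scale:
how many kidney failures, dialysis starts, deaths and euros does it cost —
or save — to treat 15 %, 50 % or 90 % of the eligible CKD G3–G5 population
with an SGLT2i over ten years?

## The model

Patients live on the 18-state KDIGO grid — six eGFR categories
(G1 ≥ 90, G2 [60, 90), G3a [45, 60), G3b [30, 45), G4 [15, 30), G5 < 15
mL/min/1.73 m²) crossed with three albuminuria categories (A1 < 30,
A2 [30, 300], A3 > 300 mg/g) — plus haemodialysis, peritoneal dialysis,
transplant and death. Annual cycles update the disease markers:

- eGFR declines by a covariate-adjusted linear slope
  (age, diabetes, hypertension, SBP, HbA1c, albuminuria category, plus a
  patient-level Gaussian random effect), UACR grows multiplicatively;
- death is drawn from `p = 1 − exp(−h(age) · RR(G, A) · c)` — an
  age-indexed baseline hazard times a monotone KDIGO relative-risk grid,
  with `c` a calibration multiplier;
- kidney failure is entry into G5; patients in G5 initiate KRT with an
  annual probability, split over modalities, and then follow a
  row-stochastic annual transition matrix;
- cardiovascular and other complications are annual Bernoulli draws from
  log-linear rate models.

Treatment is *fully mediated* through the markers: while on drug the
chronic eGFR slope is multiplied by `m < 1`, a one-time acute eGFR dip is
applied at initiation (reversed on discontinuation), UACR is reduced
relatively, SBP and HbA1c are shifted. Treatment status itself is never a
covariate of any risk equation. Discontinuation leaves no residual effect.

A scenario simulates two arms — everyone treated, no one treated — on the
identical population with common random numbers and combines them
proportionally: `outcome(u) = u · treated + (1 − u) · untreated`. The
national layer adds one incident eligible cohort per year (floor rule:
eligible = ⌊0.2675 · CKD population⌋) and removes deaths before each year's
eligibility count. Economics follow budget-impact conventions: undiscounted
EUR (7.46 DKK/EUR, price year 2024), state + event + drug costs,
age-adjusted state utilities with one-time event disutilities, and

```
NMB = λ · ΔQALY − ΔCost,    λ = €24,178 / QALY.
```

The shipped parameter fixture (`src/ckdsim/data/default_parameters.yaml`)
is calibrated so the 15 %-uptake base case reproduces the published Danish
anchors: 10-year kidney-failure risk 8.5 % and mortality 54.3 % on a
10,000-patient prevalent cohort.

## Worked example

```python
import ckdsim as ck

bundle = ck.load_parameters()
res = ck.simulate_closed_cohort(bundle.prevalent_cohort, bundle,
                                n_patients=10_000, horizon=10, seed=1, uptake=0.15)
```

printed via `examples/03_closed_cohort_outcomes.py`:

```
10-year outcomes, closed prevalent cohort (fractions):
  uptake 15%: KF risk 0.089, mortality 0.551
  uptake 50%: KF risk 0.068, mortality 0.544
  uptake 90%: KF risk 0.045, mortality 0.535
```

Reading: at the current 15 % uptake, 8.9 % of the eligible prevalent cohort
reaches kidney failure within ten years and 55 % die; near-full uptake
halves the kidney-failure risk. The national base case
(`examples/04_base_case_scenarios.py`) runs three uptake scenarios on the
dynamic population and prints the accumulated outcome table plus:

```
90 % vs 15 % uptake over 10 years: dQALY 6,044, dCost -67.5 MEUR, NMB 213.6 MEUR
```

i.e. treating 90 % instead of 15 % of eligible patients yields ~6,000 extra
quality-adjusted life-years *and* saves money over ten years. The other
examples cover cohort synthesis, single-patient trajectories, sensitivity
presets (incidence range, 57 % observed mortality, +25 % eligible, 80 %
effect, 80 % drug-price cut) and the KRT capacity flag table — which shows
the dialysis/transplant pool exceeding the 2,500–2,700 patient capacity
band within five years at status-quo uptake.

A thin CLI wraps the same functions:

```bash
ckdsim base-case --out out/ --seed 1
ckdsim sensitivity price_20 --out out_sens/
ckdsim capacity-report --out capacity.csv
```

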