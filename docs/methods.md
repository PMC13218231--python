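# ckdsim methods note

This note documents the model as implemented: its structure, parameter
provenance, calibration, numerical conventions and limitations.

## Model structure

**States.** 18 KDIGO grid states (G1–G5 with G3 split, × A1–A3), three KRT
states (haemodialysis, peritoneal dialysis, transplant) and absorbing
death. Boundary conventions are bit-exact and fixed: eGFR categories are
half-open `[lower, upper)` with G1 closed below at 90; A2 is closed at both
printed bounds (30 and 300 mg/g). Classification is total and single-valued
on the positive quadrant (property-tested).

**Cycle.** One year, no half-cycle correction. The within-cycle order is
fixed: entry/initiation → discontinuation → progression (age, marker
drifts, slope, UACR growth, reclassification) → death → kidney failure and
KRT → complications → accrual. Death is evaluated first among events; a
patient who dies in a cycle accrues no events, costs or QALYs for that
cycle. This order is a modelling choice made for reproducibility; the
alternative (events before death) would slightly raise event counts and
costs but none of the monotonicity properties.

**Progression.** Untreated annual eGFR change is
`slope = β₀ + β_age (age−75)/10 + β_dm·DM + β_ht·HT + β_sbp (SBP−132)/10 +
β_hba1c (HbA1c−5.9) + β_A2·[A2] + β_A3·[A3] + b_i`, with patient random
effect `b_i ~ N(0, σ_b²)`, clamped at zero: default dynamics never raise
eGFR. UACR grows 4 %/year (multiplicative); SBP drifts +0.3 mmHg/yr and
HbA1c +0.01 %/yr. eGFR is floored at 2 mL/min/1.73 m² and UACR capped at
5,000 mg/g to keep the state space physical.

**Treatment.** The SGLT2i effect is mediated entirely through the markers:
chronic slope multiplier `m` (calibrated, 0.62), acute dip 2.0 mL/min
applied once at initiation and reversed at discontinuation (the dip is
haemodynamic, not structural), UACR −30 % while on drug, SBP −2.6 mmHg,
HbA1c −0.1 %. These magnitudes are assumptions in line with the large
kidney-outcome trial evidence for the class; the chronic multiplier is set
by calibration (below). Annual discontinuation 5 % with no residual
effect. `effect_scale` multiplies every component; 0 reproduces the
untreated clinical trajectory exactly (tested), 0.8 is the reduced-effect
sensitivity. Eligibility is G3a–G4; treatment is never initiated in G5 and
ceases on G5 entry (no dip reversal at that point — haemodynamic recovery
at kidney failure is ignored as second-order). Treatment-attributable
adverse events (1 %/yr while on drug) carry small costs/disutilities and
are deliberately *not* scaled by `effect_scale`, which is a benefit-
strength dial.

**Mortality.** `p = 1 − exp(−h(age) · RR(G, A) · c)`. The age baseline is a
Gompertz-shaped table (doubling roughly every 8 years); the 6×3 relative-
risk grid is monotone in worse G and worse A (validated at load). Neither
the baseline level nor the grid values are published for the source
population, so their *shape* is an assumption and their *level* is set by
the calibration multiplier `c`. KRT states carry their own death
probabilities inside the KRT transition matrix.

**Kidney failure and KRT.** KF is first entry into G5 while alive. In G5,
KRT initiates with annual probability 0.35, split 0.56/0.21/0.23 over
HD/PD/pre-emptive transplant; modality switches follow a row-stochastic
matrix with constant transplant probabilities and graft failure returning
to HD. Each modality entry is counted as an initiation (so modality
initiations can exceed KF persons); the "KF + KRT" report row counts each
person once, at KF or — for patients already in G5 at model entry — at
first KRT initiation.

**Events.** Annual probabilities are `1 − exp(−exp(lp))` with `lp`
log-linear in age, (treatment-effective) SBP and HbA1c, a G-category offset
(KRT states use the G5 offset) and comorbidity flags. Coefficients are
fixture assumptions chosen to give plausible Danish-elderly-CKD base rates
(MACE ≈ 1.2 %/yr, new-onset HF ≈ 0.5 %, CVD hospitalisation ≈ 3.4 % at the
cohort reference point). New-onset HF, incident diabetes and incident
hypertension can occur at most once (they set the corresponding flag);
MACE and CVD hospitalisation are recurrent. Treatment status is
structurally excluded from every event model — mediation only. An optional
complication-to-progression feedback was considered and left out: the
source magnitudes are unknown, and a guessed feedback would only add
unverifiable coupling.

## Population dynamics

Eligibility uses a single floor convention:
`⌊251,946 × 0.2675⌋ = 67,395` national eligible in 2026 and
`⌊27,816 × 0.2675⌋ = 7,440` incident eligible per year; the prevalent
eligible cohort is the difference, 59,955. The eligible pool is simulated
patient-level at `microsim_scale` simulated persons per represented person
(default 0.1668 ≈ 10,000 prevalent patients per arm); one incident cohort
enters at the start of every year, after the previous year's deaths have
been removed. Each scenario is two arms under common random numbers —
every hazard stream is keyed by (seed, hazard, year) and indexed by a
stable patient id — combined by proportional uptake weighting, which makes
the three base scenarios differ only in a scalar and guarantees monotone
contrasts. Non-eligible CKD patients (73.25 %) are not microsimulated; the
national projection applies the eligible pool's simulated annual death
rate to the whole CKD population and adds the configured incidence.
Reports cover eligible patients only.

Report columns sit at model years 1/6/10 and are labelled start year,
start +5 and start +10 (2026/2031/2036), following the source table's
calendar labels; note those labels are one year ahead of a strict
"start + k − 1" reading for the final column.

## Costs, utilities, NMB

All amounts in EUR at the fixed 7.46 DKK/EUR rate, price year 2024, no
discounting. Stage and PD/transplant costs are printed as ranges; the
point value is configurable with the midpoint as default and bounds
enforced (HD €63,455, immunosuppression €10,678, SGLT2i €567/yr vs
standard care €13/yr are printed points). CVD events carry an acute cost
in the event year and an open-ended annual follow-up while alive (baseline
CVD history also generates follow-up costs); other complications are
costed per event, annually after first occurrence (anaemia, mineral-bone
disorder) or in the first year only (incident diabetes/hypertension), per
the schedule's timing rule — the per-event assignment is a config
decision, not an inference. `price_multiplier` (0.2 in the price
sensitivity) applies to the SGLT2i cost only.

QALYs: state utility (G1…G5 0.87…0.70; HD 0.57, PD 0.62, transplant 0.73 —
fixture values standing in for unpublished source utilities, overridable)
× the age-specific population utility curve, minus one-time event
disutilities in the cycle of occurrence, floored at zero. The age curve
bounds the age-adjusted utility by the population norm by construction.
`NMB = λ·ΔQALY − ΔCost` holds to machine precision as an identity of the
comparison layer.

## Synthetic cohorts

The registry data exist only as marginals, so cohorts are synthesised:
stage from the printed distribution, eGFR uniform within the stage bounds
then iteratively mean-shifted (clipped inside bounds) toward the printed
mean; UACR lognormal matched to the printed mean (σ = 0.9); other
continuous factors truncated normal with the location solved so the
truncated mean hits the target (defaults: age SD 10, BMI 5, SBP 15,
cholesterol 35, HbA1c 0.8); comorbidities independent Bernoulli. Two
caveats the tests make explicit: (i) the printed prevalent mean eGFR (56)
exceeds the maximum mean compatible with the printed stage shares (≈ 53.7),
so the generator attains the feasible ceiling, not 56; (ii) no albuminuria
category split is published for the Danish CKD population — the lognormal
split is an assumption, and results involving the A-dimension inherit it.
The generator does not model covariance between risk factors, secular
trends in case mix, or diagnosis under-ascertainment; passing tests
therefore validate the model mechanics against its stated marginals, not
against individual-level registry reality.

## Calibration

The unpublished source progression equations are replaced by the
parameterisation above, with three scalars set by bisection on a
10,000-patient prevalent closed cohort (both arms, common random numbers,
10 years): the mortality multiplier `c` targets 54.3 % weighted 10-year
mortality at 15 % uptake; the baseline slope β₀ targets 9.3 % untreated
KF risk; the chronic slope multiplier `m` targets 4.0 % treated KF risk —
the pair that makes the uptake-weighted KF risks land at 8.5/6.6/4.5 % for
15/50/90 % uptake. Frozen values: `c = 1.638`, `β₀ = −2.148`, `m = 0.62`
(fixture version 2026.1). The relative-risk grid contrast was chosen so
the treated-vs-untreated mortality spread stays near the published ≈ 1 pp
per 0.75 uptake. `calibrate_mortality` re-runs the same bisection at run
time for the 57 %-mortality sensitivity; monotonicity of simulated
mortality in `c` under fixed uniforms makes the search exact up to
Monte-Carlo granularity, and the result is verified on an independent
seed.

## Numerical conventions and problem sizes

- Seeds: every random stream derives from the scenario seed via
  `SeedSequence([seed, stream, year])`; identical seed ⇒ bit-identical
  outputs (tested at the CSV byte level).
- Rounding: simulated counts are rescaled to represented persons and
  rounded only in the report layer; machine-readable outputs keep full
  precision.
- Default problem sizes: 10,000 prevalent + 1,241 incident simulated
  patients per year per arm, 10 annual cycles — a three-scenario base case
  runs in about a second, and the shipped test suite and acceptance script
  use these sizes throughout.
- Degenerate inputs: non-normalizable stage distributions, negative means,
  malformed KRT rows and non-monotone risk grids are rejected at load with
  the offending field named; microsimulations below 100 patients are
  refused (Monte-Carlo error would dominate).

## Known limitations

- Treatment-effect magnitudes come from a single trial programme and are
  partly calibrated rather than estimated; the model is most trustworthy
  near the calibrated base case.
- Event-rate coefficients, utilities and event-level costs are documented
  assumptions; absolute cost levels (especially the CVD category) should
  be read as internally consistent rather than externally validated —
  *incremental* results between uptake scenarios are the intended output.
- Constant transplant probabilities mean fewer transplants when fewer
  patients reach KF; with fixed real-world transplant capacity this
  overstates dialysis needs under high uptake.
- No albuminuria-based eligibility, no G1–G2 population, no period
  effects, no competing non-CKD morbidity beyond the mortality surface.
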