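# Methods

## Model structure and assumptions

The model is a discrete-time (1-year cycle), patient-level state-transition
simulation of SCA1 over a lifetime horizon.  Severity is a continuous SARA
score in [0, 40]; health states are intervals of that score (pre-ataxic
0–2, slight >2–14, moderate >14–26, severe >26–34, end-stage >34), so the
state process inherits monotone progression from the score: regression to
an earlier state is impossible.  All individuals enter at SARA 0.

Each individual carries one progression rate, constant for life, drawn
from Normal(1.83, 0.194²) SARA points/year; the sd is back-solved from the
meta-analytic 95% CI (1.45–2.21) as `(hi − lo)/(2·1.959964)`, and
non-positive draws are redrawn.  A Normal on the mean is the minimal
reading of "sampled from the mean rate (95% CI)"; heterogeneity beyond the
reported CI (CAG-repeat length, non-linear progression) is deliberately
not modelled.

### Cycle ordering

Within a cycle, in a single code location (`engine.simulate_patient`):

1. the state occupied during the year is read from the SARA score at
   cycle start — outcomes accrue for that state;
2. treatment status is updated (start when the score satisfies the
   strategy's state-entry condition; stop permanently once the score
   exceeds the stop boundary; no restart);
3. death is drawn with the annual probability at the cycle-start score;
   a death terminates the trace *after* this cycle (the year is lived);
4. the score advances by `rate × (1 − effectiveness·on)`; the cycle in
   which the score first reaches 40 is the last cycle lived ("death
   within one year" at the scale ceiling — e.g. a deterministic
   1.83/year progressor with other mortality switched off lives
   ⌈40/1.83⌉ = 22 cycles).

No half-cycle correction is applied (plain yearly cycles).  The death
draw uses the cycle-start score because the survival inputs are indexed
by current severity; age is not a mortality input (the underlying
nomogram analysis found its impact negligible for SCA1).

### Mortality conversion

Below SARA 14 an annual background probability applies (default
0.001/year, standing in for a general-population norm in the 35–44 age
band; **no published value is printed for this input — it is a config
field users should set from their jurisdiction's life table**).  From
SARA 14 a 5-year survival S₅ is interpolated linearly between table knots
and converted as `p = 1 − S₅^(1/5)`; the inverse `(1−p)⁵` recovers S₅ to
machine precision.  Linear interpolation is used because the source
nomogram is continuous and no functional form is published.

### Treatment strategies

Five start/stop rules: full treatment (start pre-ataxic, lifelong), start
at slight (score > 2), start at moderate (score > 14), stop after
moderate (stop once score > 26), stop after severe (stop once score
> 34), each at effectiveness 5–50% in 5% steps.  Effect ceases
immediately at stop.  Usual care is represented as a strategy that never
administers therapy; a treated strategy at effectiveness 0 therefore
reproduces the usual-care *health trajectory* bit-for-bit while its
treatment flags still record (inert) drug administration — trace-identity
checks compare the trajectory fields.

### Common random numbers

Patient *i*'s generator is spawned from the master seed
(`SeedSequence(seed).spawn(n)[i]`); the rate draw comes first and exactly
one uniform is consumed per cycle, so stream positions are identical
across strategies.  Contrasts are therefore paired: under a monotone
death-probability table, higher effectiveness can never shorten any
individual's life, and incremental CIs use per-patient differences.

## Economic parameters

| parameter | default | units | source of range |
|---|---|---|---|
| utilities (pre→end) | 0.94, 0.74, 0.65, 0.38, 0.16 | — | 95% CIs for the last four; pre-ataxic is a population norm without CI |
| annual costs (pre→end) | 110.50, 2041.78, 9686.13, 39301.28, 66283.56 | €2020/yr | ±20% in DSA |
| QALY discount | 0.015 | /yr | scenario 0–0.05 |
| cost discount | 0.04 | /yr | scenario 0–0.05 |
| WTP threshold λ | 80,000 | €/QALY | — |

Costs are totals of weighted resource-use line items
(`unit_cost × annual_use × fraction_of_patients`), summed exactly in
decimal arithmetic and rounded half-up to the cent only at the total.
Discounting uses exponent t = 0 for the entry year (first year
undiscounted); this convention is not dictated by the source material and
is configurable via the accrual code.  Cohort CIs are normal
approximations (mean ± 1.959964·sd/√n).  Treatment years count whole
cycles on therapy (the yearly cycle admits no partial years);
`yearly iNMB = iNMB / mean treatment-years`.

## EQ-5D-3L utilities

`eq5d.eq5d_index` scores a five-dimension, three-level profile with an
additive tariff: anchor 1.0, minus a constant once any dimension exceeds
level 1, per-dimension level decrements, and an "N3" term once any
dimension is at level 3.  The bundled `valueset_nl_3l.csv` carries the
published Dutch tariff structure with coefficients entered from the
valuation literature — editable, user-verifiable input data (worst
profile 33333 scores −0.329).  Visit-level scores are grouped by
`sara_to_state` and averaged per state; visits are treated as independent
by default, with a clustered option that collapses repeat visits to
per-patient means first (the original derivation's clustering choice is
not documented).

## Synthetic inputs

Two inputs are generated rather than shipped from data:

* **Visit dataset** (`synthetic.generate_visits`): 479 visits over 117
  patients split 186/193/77/23 across slight/moderate/severe/end-stage,
  SARA uniform within each state's interval, and for each visit the
  profile (of the 243) whose index is nearest a Normal(target mean, sd)
  draw; sds are back-solved from the published per-state CIs (0.174,
  0.177, 0.291, 0.245).  Patients are assigned round-robin (no
  within-patient correlation by default; `cluster_sd` adds one).  The
  generator emulates the marginal per-state utility structure only — not
  longitudinal trajectories, dimension-pattern realism, or missingness —
  so passing recovery tests show the scoring/aggregation pipeline is
  unbiased at the published sample sizes, not that real EUROSCA data
  would reproduce them.
* **Survival table** (`synthetic.generate_survival_table`):
  S₅(s) = 0.98·(1 − x)^γ with x = (s−14)/26 on integer knots 14…40,
  strictly decreasing to 0 at SARA 40.  The shape γ is the single degree
  of freedom; `calibrate_survival_shape` finds it by Brent's method so
  the usual-care cohort's mean survival from model entry equals 16.59
  years on the full 10,000-patient run (bundled value γ = 1.2089,
  reproducing 16.54–16.59 years across seeds).

### What the stand-in does and does not pin down

Calibrating one shape parameter to one survival target leaves the *where*
of deaths along the severity course free, and downstream magnitudes are
sensitive to exactly that: with the bundled table the model yields
usual-care QALYs of 10.03 and mean costs of ~€105k, a full-treatment@50%
QALY gain of 6.32 and survival gain of 11.4 years — the right magnitudes
but not the published point values (10.44, ~€119k, 6.68, 13.59), and the
two top-ranked strategies by total iNMB (full treatment vs stop-after-
severe, published gap 0.2%) can swap order.  Structure-driven results —
cost-table totals, the iNMB identity, null-effect equivalence, all
monotonicities, closed-form mortality conversion, extreme-value behaviour
and the qualitative DSA/scenario directions — do not depend on the
stand-in.  Users with access to the original nomogram values should
replace `survival_5yr_synthetic.csv`.

## Numerical choices

* Rate truncation by redraw (not clipping); degenerate CI ⇒ deterministic
  rate.
* Survival-table validation requires strict knot ordering, values in
  [0, 1], non-increasing survival, and coverage of [14, 40].
* Boundary scores map to the less severe state (SARA 14 is slight),
  following the `> x` interval notation; `state_index` uses left bisection.
* DSA excursions hold the master seed fixed; the progression-rate
  excursion translates mean and CI together so the sampled sd is
  unchanged; whether the original analysis also rescaled the sd is not
  documented.  Utility/cost excursions bypass the monotone-ordering
  validation (CI bounds may cross adjacent states' point values).
* Tornado swings are computed from two full paired reruns per parameter —
  no shortcut recomputation — and verified in tests against a trace-level
  brute-force oracle.
* Per-state cost DSA is the default; a joint all-states mode exists
  (`--joint-costs`) since the original description is ambiguous.

## Problem sizes

Defaults follow the study conditions: 10,000 patients per arm, 51 arms
for the full grid, lifetime horizon (~17–30 cycles/patient).  Tests
exercise structural properties on 200–2,000-patient cohorts, which those
properties do not depend on; the calibration unit test uses 800 patients
against the ±0.5-year tolerance.  The full grid runs in well under a
minute per ten arms on one CPU.

## Known limitations

Constant individual progression rates and uniform treatment effect;
healthcare-payer perspective only (no productivity/societal costs, which
a recent ataxia cost-of-illness study suggests may exceed direct costs);
no probabilistic sensitivity analysis (one-way deterministic only, as in
the source model); mortality below SARA 14 is a single background
probability, not age-dependent; and the survival stand-in discussed
above.
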