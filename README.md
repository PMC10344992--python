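# sca1cea

Patient-level cost-effectiveness microsimulation for disease-modifying
therapy in **spinocerebellar ataxia type 1 (SCA1)**.

SCA1 is a rare, dominantly inherited neurodegenerative ataxia with no
disease-modifying treatment; gene-targeted therapies (e.g. antisense
oligonucleotides) are in development and likely to be expensive.  This
package implements an early health-economic model that asks: *if a therapy
slowed SARA progression by 5–50%, what would it be worth — in QALYs,
survival, and maximum cost-effective price — under different start/stop
strategies?*  It is aimed at health-economic modellers and ataxia
researchers who want a reproducible, scriptable version of this class of
model with editable parameters.

## The model

Disease severity is the SARA score *s* ∈ [0, 40], partitioned into five
health states: pre-ataxic (0–2), slight (>2–14), moderate (>14–26), severe
(>26–34) and end-stage (>34) ataxia, plus absorbing death.  A cohort of
10,000 individuals starts at *s* = 0; individual *i* progresses at a
constant rate rᵢ ~ N(1.83, σ²) SARA points/year (σ back-solved from the
95% CI 1.45–2.21; truncated at 0), reduced by a factor (1 − e) while on
treatment with effectiveness e.  Yearly cycles; no regression to earlier
states.

Mortality per cycle at score *s*:

* *s* < 14 — an annual background probability (general-population norm);
* 14 ≤ *s* < 40 — `p = 1 − S₅(s)^(1/5)` where S₅ is a 5-year survival
  probability interpolated from a lookup table (nomogram-style);
* *s* = 40 — death within one year.

Outcomes per strategy: discounted QALYs (state utilities 0.94/0.74/0.65/
0.38/0.16, 1.5%/yr) and discounted healthcare costs (state costs €110.50
… €66,283.56/yr built from resource-use line items, 4%/yr).  Against
usual care, with a willingness-to-pay threshold λ = €80,000/QALY:

    iNMB = λ·ΔQALY − ΔCost        yearly iNMB = iNMB / mean treatment-years

Because therapy costs are excluded, iNMB is the maximum cost-effective
therapy price.  Strategies are compared under common random numbers
(identical per-patient streams), so contrasts are paired.  One-way
deterministic sensitivity analysis (costs ±20%, utilities and progression
rate at CI bounds) and 0%/5% discount scenarios are included.

**Important:** the published SARA-indexed 5-year-survival table behind the
mortality inputs is not publicly printed.  The bundled
`survival_5yr_synthetic.csv` is a synthetic stand-in — a smooth monotone
family calibrated so usual-care mean survival is 16.59 years — and all
simulation magnitudes are conditional on it (see `docs/methods.md`).

## Worked example

```python
from sca1cea import default_config, paper_strategies, USUAL_CARE, incremental
from sca1cea.report import run_strategy_arm

cfg = default_config()                       # 10,000 patients, seed 2023
_, usual = run_strategy_arm(cfg, USUAL_CARE)
full50 = paper_strategies(0.5)[0]            # start pre-ataxic, never stop
_, arm = run_strategy_arm(cfg, full50)
inc = incremental(arm, usual, cfg.econ)
print(f"usual care: {usual.mean('survival_years'):.2f} y, "
      f"{usual.mean('qalys'):.2f} QALYs, €{usual.mean('costs'):,.0f}")
print(f"full treatment @50%: +{inc.delta_qalys:.2f} QALYs, "
      f"ΔC €{inc.delta_costs:,.0f}, iNMB €{inc.inmb:,.0f}")
```

prints

```
usual care: 16.59 y, 10.03 QALYs, €104,864
full treatment @50%: +6.32 QALYs, ΔC €-19,942, iNMB €525,581
```

i.e. under the bundled (stand-in) mortality table, a lifelong therapy at
50% effectiveness adds 6.32 QALYs per patient, *saves* about €20k of
care costs, and would be cost-effective up to a total price of ~€526k.

The same workflow from the shell:

```bash
sca1cea run --seed 2023 --out results            # 51 arms + plots
sca1cea dsa --seed 2023 --out results            # tornado + discount scenarios
sca1cea gen-data --seed 0 --out synthetic        # synthetic inputs
```

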