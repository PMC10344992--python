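# Default model configuration.
#
# Health states on the SARA scale (0-40): pre-ataxic 0-2, slight >2-14,
# moderate >14-26, severe >26-34, end-stage >34.
states:
  boundaries: [2, 14, 26, 34]

# Annual SARA progression (points/year) with its meta-analytic 95% CI;
# per-patient rates are Normal(mean, sd) with sd back-solved from the CI.
progression:
  mean_rate: 1.83
  ci_low: 1.45
  ci_high: 2.21

mortality:
  # NOTE: the bundled 5-year-survival table is a SYNTHETIC stand-in for a
  # published survival nomogram (which is not reproduced here).  Its shape
  # parameter was calibrated so the usual-care cohort's mean survival from
  # model entry is 16.59 years; replace the CSV with nomogram values if
  # you have them.
  survival_table: survival_5yr_synthetic.csv
  # Annual background death probability below SARA 14.  The source model
  # cites general-population norms (age band 35-44) without printing a
  # number; 0.001/year is a placeholder of that magnitude — EDIT to your
  # jurisdiction's life-table value.
  background_annual_prob: 0.001
  background_below_sara: 14
  certain_death_sara: 40

# Per-state EQ-5D-3L utilities.  The pre-ataxic value is a population
# norm and carries no CI; the others derive from visit-level study data.
utilities:
  pre_ataxic: {value: 0.94}
  slight: {value: 0.74, ci_low: 0.72, ci_high: 0.77}
  moderate: {value: 0.65, ci_low: 0.62, ci_high: 0.67}
  severe: {value: 0.38, ci_low: 0.32, ci_high: 0.45}
  end_stage: {value: 0.16, ci_low: 0.06, ci_high: 0.26}

# Annual healthcare costs per state, built from weighted resource-use
# line items (2020 euros).
costs:
  table: costs.csv

discounting:
  qaly_rate: 0.015
  cost_rate: 0.04

# Willingness-to-pay threshold (euros per QALY).
wtp_threshold: 80000

simulation:
  n_patients: 10000
  cycle_length: 1
  seed: 2023
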