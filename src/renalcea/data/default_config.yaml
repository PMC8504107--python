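# Base-case model configuration: the published parameter set of the Renal
# Health Program cost-effectiveness analysis (Lima, Peru). All currency in
# USD, time in years. Survival parameters are the published three-decimal
# values; treatment/dialysis costs are the precise per-patient figures
# rather than their rounded integer counterparts.
model:
  n_cycles: 30
  cycle_length: 1.0
  discount_rate: 0.03
  cohort_size: 1000
  utility_ckd: 0.84
  utility_dialysis: 0.65
  wtp_per_capita_gdp: 6571.0

survival:
  dialysis:
    lam: 0.008
    gamma: 0.938
    hazard_ratio_rhp: 0.42
  death:
    lam: 0.043
    gamma: 1.143
    hazard_ratio_rhp: 1.0
  dialysis_to_death: 0.05

costs:
  rhp_treatment_annual: 531.18
  soc_treatment_annual: 45.18
  dialysis_annual: 13458.79
  rhp_initial: 30412.0
  rhp_operational_annual: 4995.0

psa:
  n_iterations: 1000
  seed: 2021  # mandatory; override from the CLI for fresh Monte Carlo draws
  ranges:
    hr_dialysis:          {low: 0.21,   high: 0.71}
    hr_death:             {low: 0.88,   high: 1.13}
    lambda_dialysis:      {low: 0.007,  high: 0.009}
    gamma_dialysis:       {low: 0.925,  high: 0.952}
    lambda_death:         {low: 0.034,  high: 0.053}
    gamma_death:          {low: 1.098,  high: 1.193}
    rhp_treatment_annual: {low: 451.50, high: 610.86}   # +/- 15%
    soc_treatment_annual: {low: 38.40,  high: 51.96}    # +/- 15%
    dialysis_annual:      {low: 11439.97, high: 15477.61}  # +/- 15%
    utility_ckd:          {low: 0.756,  high: 0.924}    # +/- 10%
    utility_dialysis:     {low: 0.585,  high: 0.715}    # +/- 10%
    discount_rate:        {low: 0.0,    high: 0.05}

threshold:
  bracket: [0.0, 20000.0]
  tolerance: 0.005
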