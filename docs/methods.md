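# Methods

## Model structure and assumptions

The engine is a deterministic Markov cohort model with three states —
pooled CKD (KDIGO 1–4), dialysis, death — run over 30 annual cycles for a
closed cohort that starts entirely in CKD. The Markov property is assumed
throughout: transition probabilities depend only on the current state and
the cycle index, never on time already spent in a state (no tunnel
states). Consequences:

- Exits from CKD are *time-varying*: per-cycle probabilities derive from
  two cause-specific Weibull curves S(t) = exp(−λ t^γ) via the
  conditional-survival identity p(c) = 1 − S(c)/S(c−1). The two exits are
  applied simultaneously within a cycle (no within-cycle ordering); a
  validity check raises if their sum ever exceeds 1.
- Dialysis mortality is a *fixed* 0.05 per cycle regardless of time on
  dialysis. Published cohort data suggest first-year survival ≈95% with
  slow decline afterwards; a constant 5% is the memoryless approximation.
- Death absorbs, accruing zero cost and zero utility.

Accrual is at the **end of each cycle on post-transition occupancy**,
discounted by (1+r)^(−t); no half-cycle correction is applied. A person
entering dialysis during cycle t therefore pays a full dialysis year and
receives the dialysis utility for cycle t, and a person dying during cycle
t accrues nothing for it. YL is defined as discounted person-years in the
CKD state (years lived free of dialysis); QALYs weight CKD and dialysis
person-years by 0.84 and 0.65. The dialysis cost and utility apply to
every person-cycle spent in the state (prevalence basis), not only the
incident cycle.

The cohort size (1000) affects only the allocation of the program's fixed
costs; occupancy dynamics are expectation fractions. The program's
one-time investment is charged at cycle 0 undiscounted; operational costs
accrue at cycles 1..30 discounted; both are divided by the *initial*
cohort — they are fixed costs with negligible marginal cost per patient,
so they do not scale with survivors (a config-free design choice; accruing
them only while patients remain alive would change the per-person program
cost by well under a dollar a year and is intentionally not implemented).

## Parameters

| Parameter | Default | Units | Source of the default |
|---|---:|---|---|
| λ, γ (CKD→dialysis) | 0.008, 0.938 | 1/yr^γ, — | published fit (3-decimal print) |
| λ, γ (CKD→death) | 0.043, 1.143 | 1/yr^γ, — | published fit (3-decimal print) |
| HR dialysis / death | 0.42 / 1.0 | — | effect estimates (CIs 0.21–0.71, 0.88–1.13) |
| p(dialysis→death) | 0.05 | /cycle | literature, memoryless approximation |
| Treatment cost RHP / SoC | 531.18 / 45.18 | USD/person-yr | institutional costing (precise values; the rounded stage table reconstructs ≈527) |
| Dialysis cost | 13,458.79 | USD/person-yr | 156 sessions × ($79.09 + $6.80) + 4 visits × $14.84 ≈ 13,458.20; the precise published total is the input |
| Program costs | 30,412 + 4,995/yr | USD/cohort | institutional costing |
| Utilities CKD / dialysis | 0.84 / 0.65 | — | standard-gamble literature values |
| Discount rate | 0.03 | /yr | guideline value; PSA varies 0–0.05 |
| Horizon | 30 × 1 yr | — | lifetime for a cohort aged ~60 |
| WTP anchor | 6,571 | USD/QALY | per-capita GDP (band 1–3×) |

All parameters live in a single YAML config (`renalcea/data/
default_config.yaml`); nothing numeric is hard-coded elsewhere.

### Sensitivity of results to the printed survival parameters

The published survival parameters are rounded to three decimals, which for
λ_dialysis = 0.008 means a ±6% relative slack. Because every
dialysis-related quantity is roughly proportional to this λ, the model's
headline incremental cost is very sensitive to it: with the printed values
the base case yields Δcost ≈ −$542/person, while values inside the
rounding interval (λ_d ≈ 0.0084, γ_d ≈ 0.9375, λ_m ≈ 0.0430,
γ_m ≈ 1.1435) reproduce the originally reported −$783 and both ICERs to
within 0.5%. The package deliberately ships the *printed* values — they
are the citable inputs — and treats the reported-figure gap as input
rounding, not model structure. Users calibrating to their own data are
unaffected.

## Survival calibration

`fit_parametric` fits five candidate distributions to right-censored
time-to-event data: Weibull, exponential, log-normal and log-logistic via
lifelines' univariate fitters, and a plain logistic on the raw time axis
via an in-house right-censored MLE (Nelder–Mead on (μ, log s), tolerance
1e−8; no lifelines fitter exists for that model). Cause-specific fitting
censors competing events at their observed times. Selection minimises AIC
or BIC with a fixed tie-break ordering (weibull < exponential < lognormal
< loglogistic < logistic). Distributions whose support includes negative
times may win selection but refuse conversion to (λ, γ); only Weibull and
exponential convert, via λ = exp(−intercept/scale), γ = 1/scale under the
convention S(t) = exp(−(t/exp(intercept))^(1/scale)). Only the year time
scale is implemented.

## Synthetic cohorts

The generator emulates the registry structure the calibration assumes:
independent latent Weibull times to dialysis and death per subject
(latent-failure-time competing risks), observed as the minimum together
with an administrative censoring horizon (default 5 years, the original
study window; no random loss to follow-up, matching a calibration aimed at
the core disease progression rather than attrition artefacts). Seeds are
explicit and mandatory. What passing recovery tests show: the fitting
machinery inverts its own generative assumptions at realistic sample
sizes. What they do not show: robustness to informative censoring,
covariate heterogeneity, or non-Weibull hazards present in real registry
data. Note that with a 5-year window only ~3% of subjects reach dialysis,
so λ̂_dialysis carries a ~4–6% Monte-Carlo relative error even at
n = 50,000; recovery tolerances in the tests are stated per fixed seed.

## Probabilistic sensitivity analysis

1000 iterations; every varying parameter is drawn independently and
uniformly over its configured [low, high] range (the source analysis names
ranges but not distributions; uniform is the assumption-minimal choice and
is recorded in the output metadata). The varying set: both hazard ratios,
both (λ, γ) pairs, the three treatment/dialysis costs (±15%), both
utilities (±10%) and the discount rate (0–5%); program fixed costs have no
published range and stay fixed. Deltas are reported as intervention minus
comparator, with the sign convention stated in headers. Summary statistics
use the sample (n−1) SD; RSE = SD/|mean|×100 is flagged undefined at zero
mean or a single iteration. Invalid draws (exit probabilities above 1)
would be resampled with a cap of 100 attempts; the shipped ranges never
trigger this. Iterations are bit-reproducible for a given seed.

Two cautions for interpreting dominance counts. First, mortality-HR draws
above 1 make incremental QALYs negative (the intervention arm then has
worse mortality), and dialysis-HR draws near the top of the CI erase the
cost saving — so under uniform sampling of the full CIs the dominant
fraction is far below what a point-estimate-centred sampling scheme would
give. Second, λ/γ are sampled independently although the underlying
estimates are correlated; joint sampling would narrow the spread.

## Threshold analysis

The break-even annual dialysis cost solves Δcost(d) = 0 with everything
else at base case. Both arms' cost totals are affine in d, so the root is
unique whenever the intervention accrues fewer discounted dialysis
person-years (guaranteed for HR < 1). Bisection on the configured bracket
(default [0, 20000]) runs to a $0.005 tolerance on the price axis — tight
enough that it matches the closed-form affine solve to ≤ $0.01, which is
computed alongside as a cross-check; bisection remains the primary path so
the operation generalises to non-affine parameters. A bracket without a
sign change raises with the endpoint evaluations as diagnostics.

## Numerical choices and degenerate inputs

- Transition probabilities use `expm1`, exact to 1e−12 against the
  S(c)/S(c−1) oracle; they saturate to 1.0 in floating point only for
  cumulative hazards beyond ~e±37, far outside the disease range.
- Occupancy conservation holds to 1e−12 per cycle by construction
  (the CKD update uses the complement of the summed exit probabilities).
- A censoring horizon of exactly 0 censors every synthetic subject at an
  epsilon time (1e−9 y) so times stay strictly positive.
- Cohort stage-weight sums within 2% of 1 are renormalised; larger
  deviations raise.
- Fitting data with zero events of the requested cause raises
  (degenerate likelihood) rather than returning a boundary fit.

## Limitations

- Unstratified cohort: no age/sex/stage covariates, no transplantation or
  peritoneal-dialysis states.
- Payer perspective only; no societal costs, currency conversion or
  inflation adjustment (USD throughout).
- The fixed 5% dialysis mortality and the prevalence-based dialysis
  costing are structural simplifications inherited from the memoryless
  design.
- PSA parameter independence (above) and uniform sampling are modelling
  choices, not estimated distributions.
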