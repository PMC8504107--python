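# renalcea

Lifetime cost-effectiveness modelling of a chronic kidney disease (CKD)
progression-delay program — the Renal Health Program (RHP), a secondary-
prevention case-management strategy implemented in Lima, Peru — against
standard of care, from the payer perspective.

The package is aimed at health economists and epidemiologists who want a
tested, configuration-driven, reproducible implementation of this class of
decision model: parametric survival calibration feeding a Markov cohort
model with probabilistic sensitivity and break-even analysis on top, plus a
synthetic competing-risk cohort generator so the calibration machinery can
be exercised without access to registry data.

## The model

**States.** A closed cohort starts in a pooled CKD state (KDIGO stages 1–4)
and moves through three states: CKD → dialysis → death (death also reached
directly from CKD; it is absorbing).

**Time-varying transitions.** The two exits from CKD are governed by
cause-specific Weibull survival curves S(t) = exp(−λ t^γ), with the
per-cycle (annual) transition probability given event-free entry into
cycle c:

    p(c) = 1 − S(c)/S(c−1) = 1 − exp[λ((c−1)^γ − c^γ)]

Accelerated-failure-time fits reporting (intercept, scale) convert to this
parameterisation via λ = 1/exp(intercept)^(1/scale) and γ = 1/scale.
Treatment effects enter as proportional-hazards adjustments, λ′ = λ·HR:
the intervention carries HR = 0.42 (95% CI 0.21–0.71) for progression to
dialysis and HR = 1 (0.88–1.13) for mortality. Dialysis patients die with
a fixed probability of 0.05 per cycle (memoryless).

**Accrual.** Over 30 annual cycles, end-of-cycle state occupancy accrues,
per person: costs (annual treatment cost by arm, $13,458.79 per
person-year of dialysis, and — intervention arm only — program fixed costs
of $30,412 once plus $4,995/year spread over the 1000-person cohort),
dialysis-free life years (YL), and QALYs (utility 0.84 in CKD, 0.65 on
dialysis). Everything is discounted at 3%/year; there is no half-cycle
correction. Comparison reports Δcost, ΔYL, ΔQALY, the ICERs
Δcost/Δeffect, and a dominance classification against a
willingness-to-pay anchor of 1–3× Peru's per-capita GDP ($6,571).

## Worked example

The shipped default configuration is the published base case. Running

```bash
renalcea compare
```

prints

```
| Quantity | Renal Health Program | Standard of care | Difference (RHP − SoC) |
|---|---:|---:|---:|
| Costs (USD, per person) | 9,220.08 | 9,762.33 | -542.25 |
| YL, dialysis-free (per person) | 9.51 | 9.16 | 0.35 |
| QALY (per person) | 8.18 | 8.15 | 0.03 |
| ICER: USD/YL | | | -1,564.60 |
| ICER: USD/QALY | | | -15,590.81 |
| Dominance | | | dominant |
```

Read: over a 30-year horizon the program saves $542 per person while adding
0.35 dialysis-free years and 0.03 QALYs — it is *dominant* (cheaper and
more effective), driven by avoided dialysis person-years at $13,459/year.
The negative ICERs are savings per unit of health gained. `renalcea
threshold` reports the dialysis price at which the saving vanishes
(`break-even dialysis cost: USD 12,083.82/year`): above that price the
program pays for itself on dialysis avoidance alone.

Note on published figures: the originating analysis reports a larger
saving (−$783/person, ICER −$21,660/QALY) from the same model structure.
Its survival parameters are published rounded to three decimals, and the
gap is attributable to that rounding — λ for the dialysis curve is ~0.008
with a ±6% rounding slack that propagates directly into every
dialysis-related quantity. `docs/methods.md` discusses this sensitivity.

Other entry points (`renalcea --help`): `simulate-cohort` and `calibrate`
for the synthetic-data → survival-fitting loop, `run`/`curve` for
single-arm traces and event-free survival, `psa` for the Monte Carlo
sensitivity analysis, `report` for the full pipeline with CSV/JSON/markdown
outputs and a run manifest.

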