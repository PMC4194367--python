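# renalbudget

A budget-impact model of dialysis modality mix for the England NHS payer.

End-stage renal disease patients who cannot receive a transplant need
dialysis: peritoneal dialysis (PD) at home, haemodialysis in-centre (ICHD,
conventionally 3 × 4 h sessions/week) or at home, including *high-dose* home
haemodialysis (5 × ≥4 h sessions/week). Home-based care avoids clinic
transport and uses cheaper tariffs (PD) or a fixed weekly tariff (home HD),
so the share of patients on each modality drives the payer's dialysis
budget. `renalbudget` projects that budget over five years and compares
modality-shift scenarios against current practice.

## The model

A discrete-time Markov cohort model with 28-day cycles (13 cycles per
364-day model year, 65 cycles over the 5-year horizon):

- **States:** PD, conventional ICHD, high-dose ICHD, conventional home HD,
  high-dose home HD, transplant (a single-cycle tunnel state),
  post-transplant, dead.
- **Dynamics:** per cycle, each living patient may die, receive a transplant
  (probability 0.007 per cycle for all dialysis states), or switch modality —
  at most one movement per cycle, composed as death → transplant → switch.
  Modality-switch probabilities depend on time on the current modality
  through tenure bands (0–6, 7–12, 13–18, 19+ months; a tunnel dimension)
  and on incident vs prevalent status. Graft failure (0.004 per cycle)
  returns post-transplant patients to dialysis across the scenario's
  baseline distribution.
- **Survival:** parametric survivor functions S(t) (exponential by default;
  Weibull/Gompertz opt-in, solved through user-supplied survival anchors)
  converted to per-cycle conditional death probabilities
  `q = 1 − [S(t+Δ)/S(t)]^HR`, with a hazard ratio of 0.76 for high-dose HD
  versus conventional HD. The packaged curves are synthetic stand-ins
  (documented assumptions), so headline pound totals are indicative;
  the scenario *orderings* are robust to the curve choice.
- **Population:** 22,993 prevalent patients at baseline plus 5,395 incident
  patients entering at the start of each of years 2–5.
- **Costs** (undiscounted, per payer budget-impact convention): access
  establishment, dialysis treatment tariffs, ESA (anaemia medication),
  monitoring, all-cause hospitalisation, clinic transport, transplant
  procedure and post-transplant medication.
- **Scenarios:** the current England mix (reference: prevalent 14.1% PD,
  82.0% ICHD, 3.9% conventional home HD) versus five shifts of prevalent
  and/or incident patients toward home-based care, including an increased
  £575/week tariff for high-dose home HD (scenarios 2–4) and an
  all-in-centre counterfactual (scenario 5).

A vectorised individual-patient Monte-Carlo simulator (`simulate_patients`)
re-implements the same transition process and serves as an independent
cross-check of the deterministic engine, with Monte-Carlo standard errors.

## Worked example

```python
import renalbudget as rb

inputs = rb.default_inputs()                      # packaged England parameterisation
results = rb.run_all_scenarios(inputs)
ref = results["reference"]
for sid in ("s1", "s2", "s3", "s4", "s5"):
    rep = rb.compare(ref, results[sid])
    print(f"{sid}: £{rep.total_difference:,.0f} ({rep.total_relative:+.2%})")
```

prints, under the packaged default survival curves:

```
s1: £-28,319,492 (-0.72%)
s2: £16,690,199 (+0.43%)
s3: £-54,348,664 (-1.38%)
s4: £-118,895,015 (-3.03%)
s5: £199,344,629 (+5.08%)
```

Negative numbers are five-year savings versus current practice: moving 10%
of prevalent patients to high-dose home HD under the current £456/week
tariff saves money (s1, driven by transport); the same shift at a £575/week
tariff costs more (s2); growing PD to 20–25% of prevalent patients offsets
that and saves substantially (s3, s4); treating everyone in-centre (s5) is
the most expensive option. The `examples/` scripts walk through each
capability (scenario runs, comparison, survival curves, sensitivity sweeps,
microsimulation validation); there is also a thin CLI
(`renalbudget run|compare|sensitivity|oracle|validate-config`).

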