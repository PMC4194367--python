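# Methods

## Model structure

`renalbudget` is a discrete-time Markov cohort model of the England adult
dialysis programme. Eight health states — peritoneal dialysis (PD),
conventional in-centre haemodialysis (ICHD), high-dose ICHD, conventional
home HD, high-dose home HD, transplant, post-transplant, dead — are advanced
in 28-day cycles. Short cycles suit dialysis modelling because modality
switches, transplant listing events and deaths all occur on sub-annual time
scales. A model year is 13 cycles (364 days), chosen so that incident-cohort
entry and annual cost proration fall on cycle boundaries; the 5-year horizon
is 65 cycles. The model is undiscounted, following budget-impact practice.

Occupancy mass lives on a four-way grid: health state × modality tenure in
cycles × entry cohort × entry class. Tenure is a tunnel dimension: movers
re-enter their destination state at tenure 1 and stayers increment, so the
month bands that drive duration-dependent switch probabilities (0–6, 7–12,
13–18, 19+ months, mapped as cycles 1–7, 8–13, 14–20, 21+) are a
deterministic function of the grid. The entry cohort (prevalent at cycle 0;
one incident cohort per entry year) pins down each cell's mortality clock
and its first-year/follow-up hospitalisation band exactly.

### Event ordering

Within a cycle, events compose sequentially — death first, then transplant,
then modality switch — each applied to the mass remaining after the previous
one. This guarantees at most one movement per cycle and makes every
transition row sum to one by construction. The ordering itself is a
modelling choice; with per-cycle probabilities of this size (≤ 2%) the
alternative orderings differ in the third significant figure of flows.

### Redistribution on switching

Patients who change modality are redistributed over the destination's
sub-modalities according to the scenario's prevalent baseline distribution:
PD→HD movers split across the four HD states in proportion to the baseline
HD mix; ICHD→home movers split conventional/high-dose by the baseline home
mix, and symmetrically for home→ICHD. Where a destination's baseline share
is identically zero but the switch probability is positive (the all-in-centre
scenario has no home HD), movers fall back to the conventional sub-modality
of the destination setting. Graft failures return to dialysis across the
full baseline distribution and are re-classified as prevalent (a new
modality episode, tenure reset).

### Population

22,993 prevalent patients enter at baseline, distributed per the scenario's
prevalent mix; 5,395 incident patients enter at the first cycle of each of
model years 2–5 (year 1 has no incident entry, honouring the stated design
of the analysis). The prevalent cohort's *modality* clock starts at model
start — required for the prevalent-specific 0–6-month switch rows to apply —
but its *dialysis-year* band starts at year 2+ (these patients are not in
their first year of dialysis). A config flag
(`prevalent_hospitalisation_year1`) flips the latter choice for exploration.

## Survival

Registry survivor curves for dialysis and transplant populations are not
published in reusable form, so the package ships a configurable parametric
stand-in: exponential, Weibull or Gompertz survivor functions solved through
survival anchors (e.g. S(1y), S(5y)). Defaults are exponential with
S(1y) = 0.88 (dialysis) and S(1y) = 0.97 (transplant) — labelled assumptions
in all output metadata, never presented as published values. The exponential
default makes the mortality clock irrelevant (constant hazard), which
sidesteps the unstated question of where a prevalent patient's survival
clock should start; non-constant families are opt-in, and with them the
model uses time since model entry (prevalent) or dialysis start (incident)
for dialysis states and time since transplant for the transplant states.

Per-cycle death probabilities are proportional-hazards transforms of the
conditional survivor ratio, `q(t; HR) = 1 − [S(t+Δ)/S(t)]^HR` with Δ = 28
days. The high-dose hazard ratio 0.76 (range 0.57–0.95) applies to both
high-dose states; the home setting itself confers no survival difference
(HR 1.00). Transplant and post-transplant states share the transplant curve.

Because the survivor curves are assumptions, the five-scenario comparison is
validated on *signs and orderings* (which scenarios save, which cost, and
their ranking), which hold for any monotone survivor function of plausible
level: transport and tariff differences dominate, and survival enters all
scenarios symmetrically up to the high-dose share.

## Costs

Eight components accrue per cycle on start-of-cycle occupancy (no half-cycle
correction):

| component | rule | default |
|---|---|---|
| treatment, ICHD | per-session × sessions/week × 4 weeks | £147 × 3 (or 5) × 4 |
| treatment, home HD | weekly tariff × 4 (fixed, session-independent) | £456 (£575 in s2–s4 for high dose) |
| treatment, PD | APD-share-weighted per-day × 28 | (0.5×£52 + 0.5×£46) × 28 |
| ESA | dose/1,000 × £5.09 × 4 weeks | 6,705 u/wk HD, 3,700 u/wk PD |
| monitoring | 2 visits/yr × weighted £190 / 13 | dialysis states only |
| complications | 28-day probability × event cost | £1,904 HD / £1,596 PD events |
| transport | £46 × in-centre sessions; home-based £0 | ICHD only |
| transplant | £18,579 in the transplant cycle; £11,137/yr ÷ 13 post | event-driven |

Hospitalisation probabilities are first-year trial values (7.05% ICHD,
5.35% conventional home HD, 7.09% high-dose HD, 6.69% PD per 28 days) with
follow-up years at 0.69 × year 1 rounded at printed precision (4.86%, 3.69%,
4.89%); PD is constant across years. The high-dose row is applied to the
high-dose ICHD state as well (it has no published row and zero occupancy in
every shipped scenario). Post-transplant patients incur no hospitalisation
or ESA costs, and monitoring for them is off by default (config flag).

Access establishment is an event cost: vascular access £1,287 on entering
any HD state from outside HD, peritoneal access £1,233 on entering PD;
switches within HD are free. It is charged to incident entrants, switchers,
graft-failure returners and — by default, exposed as a flag — to the
prevalent cohort at baseline, which is consistent with the scale of the
published access totals. The weighted £147 ICHD session cost is used
directly; the £121/£152 catheter/fistula split is retained only for
sensitivity overrides.

### Sensitivity ranges

Low/high bounds follow a ±25% convention: `point × (1 ∓ 0.25)` computed in
double precision and rounded half-up at the printed precision of the
parameter. Nine published ranges do not follow this rule and are stored
verbatim as overrides (most prominently peritoneal access, £854–£1,423; also
the ICHD session sub-costs, one HD hospitalisation bound, one post-transplant
medication bound and four switch-probability bounds whose published halves
were rounded the other way). The config always carries the published values;
the convention is tested over the conforming majority. One-way sweeps re-run
a scenario pair with a single parameter at a bound, everything else at point
values; probabilistic sensitivity analysis is out of scope (no distributions
are published).

## Per-patient/year denominators

The five-year average cost per patient per year is reported under two
denominators: patient-years actually lived in the model
(Σ alive mass × 28/365.25, the default) and the cumulative-entrants
convention (Σ over years of patients entered by that year, 168,915 for the
reference population). The published description of the per-patient table is
ambiguous between the two; the entrants denominator reproduces the published
per-patient level closely, while years-lived is the more interpretable
quantity. Both are computed in every report.

## Microsimulation cross-validation

An individual-patient Monte-Carlo simulator draws each patient's entry
cohort, starting modality and per-cycle (death, transplant/graft,
switch-destination) uniforms from a dedicated substream spawned from one
global seed, so histories are reproducible and unchanged when n grows. It
uses the same composed per-cycle probabilities as the cohort engine and
aggregates occupancy and component costs with Monte-Carlo standard errors.
The cohort engine computes the exact expectation of the simulated process,
so agreement within ~3 standard errors at n = 50,000 across all states,
snapshot cycles (13, 39, 65) and cost components is the acceptance check;
the simulator is not a results engine and uses no variance reduction.

## What the synthetic defaults do and do not show

The packaged configuration reproduces the published *structure*: unit-cost
arithmetic exactly; scenario signs and orderings; the tariff linearity
identity (the two 10%-high-dose-home scenarios share bit-identical
occupancy trajectories, and their cost difference equals £119/week × 4 weeks
× high-dose-home patient-cycles exactly). Absolute pound totals depend on
the survival stand-in and land within a few percent of the published scale
under the defaults, but they are not calibrated to match, and should be read
as indicative. Real registry curves, age/gender stratification, within-PD
sub-modality dynamics, waiting-list structure for transplantation, patient
out-of-pocket costs and cost inflation are all outside the model.

## Numerical notes

- Mass is conserved to 1e-9 relative per cycle by construction; transition
  rows sum to 1 within 1e-12; ledger components partition the total exactly.
- Anchor fitting: exponential is closed-form from one anchor; Weibull
  closed-form from two; Gompertz by bracketed root-finding (Brent, xtol
  1e-14) on the cumulative-hazard ratio. Degenerate anchors (S = 1, or
  non-decreasing) are rejected with an error suggesting an alternative
  family where applicable.
- Tenure is capped at the occupancy array edge (well inside the 19+ band);
  with a non-constant transplant curve the post-transplant mortality clock
  saturates there, a documented approximation that the exponential default
  avoids.
- The survivor-ratio power is clipped to [0, 1] against round-off; a curve
  evaluated where S(t) = 0 raises (cohort extinct beyond support) rather
  than returning NaN.
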