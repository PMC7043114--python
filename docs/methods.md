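# Methods

## The model

`p2i` implements a deterministic pipeline-portfolio model for health-product
R&D. A portfolio is a set of candidates, each classified into an *archetype*
— a product class sharing per-phase assumptions — and sitting at the start
of its current development phase. Four phases are modelled: advanced
preclinical, phase I, phase II and phase III. For archetype *a* the
assumptions are, per phase *p*:

- C_{a,p} — phase cost, US$ millions,
- L_{a,p} — phase duration (cycle time), years,
- s_{a,p} — probability of success, the fraction of candidates entering the
  phase that advance to the next.

For candidate *i* entering phase e_i the model derives:

- entry probability π_{i,p} = ∏_{e_i ≤ q < p} s_{a,q} (empty product = 1) —
  the probability the candidate ever reaches phase *p*;
- launch probability λ_i = ∏_{p ≥ e_i} s_{a,p} — a *launch* is defined as
  completing phase III, before any regulatory or manufacturing steps;
- risk-adjusted phase cost π_{i,p}·C_{a,p} — the expected spend on phase
  *p*, since a funder only pays for phases the candidate reaches;
- a contiguous timeline of half-open intervals of widths L_{a,p}, starting
  at t = 0 (Jan 1 of the start year).

Portfolio outputs are per-disease and total risk-adjusted cost within the
calendar horizon, total expected launches (sum of λ_i), an annual cost and
cumulative-launch-probability schedule, and, for scenario runs, a
side-by-side per-disease comparison.

### Assumptions and scope

The model is static and deterministic: one pass per candidate, no trial
reiteration, no returning to earlier phases, no learning or efficiency
gains over time, and no differences between study settings. Expected
launches are probabilities, not integers — 0.69 expected launches means the
portfolio will most likely produce no launch inside the horizon. All costs
are undiscounted nominal US$ millions; no inflation or cost-of-capital
adjustment is applied. Costs before advanced preclinical work (basic
research through lead optimization) and after phase III (regulatory fees,
manufacturing scale-up, phase IV) are excluded, so totals understate full
development costs by design.

## Calendar accrual and launch dating

Three conventions, chosen where the underlying model family leaves the
mechanics open, are fixed as follows:

- **Time origin.** Every candidate begins its current phase at Jan 1 of the
  start year and proceeds in continuous (fractional-year) time. With the
  packaged inputs this reproduces the published first-run cumulative costs
  for 2019–2021 to essentially all printed digits.
- **Uniform within-phase accrual.** The risk-adjusted phase cost accrues at
  the constant rate π·C/L per year; a calendar year's accrual is the
  overlap-weighted sum over phases, and accrual past Dec 31 of the end year
  is discarded. Applying the risk adjustment to the whole phase — including
  its first partial year — is the only rule consistent with the published
  second-year value.
- **Launch dating.** A launch is booked in the calendar year containing the
  instant the phase-III interval ends; an end time landing exactly on a
  Jan 1 boundary counts in the earlier year (the interval is half-open).
  This matches the published 2025/2026/2028/2031 cumulative-launch steps.

Degenerate inputs: a zero-length phase deposits its full risk-adjusted cost
at its start instant, into the year containing it (the limit of uniform
accrual as L → 0). Phase-end times are rounded to 9 decimals before year
assignment so that float drift cannot move a boundary-exact launch across
years. Probabilities are stored as fractions; percent inputs are converted
on read with no hidden extra precision.

### Known numerical discrepancy vs the published tables

The published per-disease cost totals sit systematically ~0.04–0.13 US$M
(≤ 0.2%) below the closed-form risk-adjusted sums, and the published
cumulative cost series drifts from the continuous accrual rule from the
fourth year onward (published 199.9804 vs computed 199.8963 at 2022; total
470.3567 vs 470.7583). The original implementation was a spreadsheet whose
internal discretization (possibly month- or quarter-rounded phase
boundaries) is not described, so no attempt is made to emulate it: early
years are checked digit-exact, later years and cost totals to 0.5%. One
consequence: the continuous rule gives 90.39987 (5 dp) for cumulative 2020
cost where the published table prints 90.39988 — a one-unit difference in
the last printed digit. Launch probabilities are pure closed-form products
and carry no such discrepancy.

## Scenario engine

A scenario is a list of targeted overrides (archetype, phase, field,
value), applied to a copy of the parameter set; the baseline is never
mutated and repeated application is idempotent. The canonical packaged
scenario modifies only the two parameters backed by ten historical data
points — unprecedented-vaccine phase-I success probability 0.50 → 0.70 and
phase-I duration 2.0 → 1.45 years (17.4 months). The remaining internal
parameters (preclinical duration, EUR-denominated phase costs, phase-II
figures) rest on two or three data points each and ship as annotations only
(`fixtures.EVI_INTERNAL_DATA`, dumped by `p2i fixtures`); EUR values are
deliberately not converted to US$. Raising a phase's success probability
weakly raises every downstream entry probability, every λ and every
risk-adjusted downstream cost, which is why the scenario raises both
launches (0.69 → 0.72) and cost (≈ 471 → 517 US$M).

## Sensitivity analysis

"10% higher/lower" is multiplicative: every phase's probability of success
is scaled by m_s (clamped at 1.0) and/or every cost by m_c; lengths are
never perturbed. The multiplicative reading is forced by the published
extremes — a candidate with k remaining phases has λ scaled by m_s^k, and
summing over the reference portfolio gives 0.9062 at m_s = 1.1 and 0.5063
at m_s = 0.9, matching the printed 0.91/0.51, which an
additive-percentage-point reading does not reproduce. Cost-only
perturbation scales total cost exactly linearly and leaves all launch
outputs untouched. Two of the published sensitivity-table cost cells are
internally inconsistent with their own baseline (apparent transcription
slips between the two published grids); cost behaviour under perturbation
is therefore verified by exact linearity rather than against those cells.

## Synthetic portfolios

`synth.generate_portfolio` draws candidates by weighted sampling of
archetype and entry phase over a disease pool, deterministically for a
fixed seed (NumPy `default_rng`). Defaults mirror the reference
portfolio's empirical mix: archetype weights 15/2/1
(unprecedented/simple/complex) and phase weights 3/11/4/0
(preclinical/I/II/III) over the same six diseases. The generator emulates
*structure* only — it does not synthesize new archetype parameter tables
(an optional `jitter_params` mode perturbs them ±20% for property tests,
uncalibrated by construction) and it knows nothing about programme content,
correlations between candidates, or disease-specific attrition. Passing
property tests on synthetic portfolios therefore demonstrates the engine's
algebraic invariants (closed-form/accrual equivalence, monotone cumulative
series, scaling laws, aggregation identities), not the realism of any
particular assumption set.

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| per-phase cost C | US$ millions | packaged archetype table | dominant driver of totals; phase III is ~90% of a candidate's nominal cost |
| per-phase length L | years | packaged archetype table | sets accrual timing and launch year, not magnitude |
| per-phase success s | fraction | packaged archetype table | enters multiplicatively; small phase-II/III changes move launches strongly |
| horizon | calendar years | 2019–2031 | covers every packaged candidate's full timeline (longest 12.5 y) |
| sensitivity multipliers | — | (0.9, 1.1) | the conventional ±10% one-way/two-way grid |

## Problem sizes and runtime

All computations are desk-scale: 18 candidates × 4 phases × 13 years for
the reference analysis, ≤ 40 candidates in property tests, and a single
10,000-draw law-of-large-numbers check on the generator. The full test
suite runs in a few seconds; the acceptance script in well under one.

## Limitations

- No trial reiteration or backward phase transitions; real vaccine
  programmes typically repeat phase I/II trials, so costs and timelines
  here are lower bounds.
- Archetype-level parameters ignore disease- and setting-specific
  variation in cost, attrition and cycle time.
- The published spreadsheet's internal discretization is not reproduced
  (see discrepancy note above); agreement is digit-exact early and ≤ 0.5%
  elsewhere.
- Expected launches aggregate independent per-candidate probabilities; no
  correlation between candidates (shared platforms, shared funders) is
  modelled.
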