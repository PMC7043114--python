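# p2i — deterministic pipeline-portfolio modelling for health-product R&D

`p2i` estimates the funding needed to move a portfolio of candidate health
products (vaccines, drugs) from advanced preclinical development through
phase III, and the number of product launches that spending can be expected
to buy. It is written for funders, product development partnerships and
R&D policy analysts who need portfolio-level cost and launch forecasts
from a small, auditable set of per-phase assumptions.

## The model

Each candidate belongs to an **archetype** — a product class with per-phase
assumptions on cost C_{a,p} (US$ millions), duration L_{a,p} (years) and
probability of success s_{a,p} — and sits at the start of its current phase
e_i. The model is deterministic and closed-form:

- **Launch probability** λ_i = ∏_{p ≥ e_i} s_{a,p} — the chance of clearing
  every remaining phase through phase III ("launch" = completing phase III).
- **Risk-adjusted phase cost** π_{i,p}·C_{a,p}, where
  π_{i,p} = ∏_{e_i ≤ q < p} s_{a,q} is the probability of ever reaching
  phase p — the expected spend, since failed candidates stop paying.
- **Calendar accrual**: phases occupy contiguous intervals from Jan 1 of
  the start year; each phase's risk-adjusted cost accrues uniformly at
  π·C/L per year, summed into calendar years by interval overlap.
- **Expected launches** per disease and in total are sums of λ_i, with each
  launch booked in the calendar year its phase III ends.

Scenario runs apply targeted parameter overrides (archetype, phase, field,
value); sensitivity runs multiply all success probabilities and/or all
costs by ±10% (or any grid of multipliers). See `docs/methods.md` for
conventions, numerical choices and limitations.

The package ships a reference portfolio: 18 anonymized vaccine candidates
for six diseases of poverty and emerging infectious diseases (malaria,
placental malaria, leishmaniasis, shigellosis/ETEC, Nipah, Zika),
classified into simple / complex / unprecedented vaccine archetypes, with
the matching archetype parameter table and horizon 2019–2031.

## Worked example

```python
from p2i import aggregate_portfolio, evi_portfolio_fixture

result = aggregate_portfolio(evi_portfolio_fixture())
print(result.by_disease.round({"cost": 2, "expected_launches": 3}))
print(f"{result.total_cost:.2f} US$M, {result.total_launches:.2f} expected launches")
```

prints

```
                     cost  expected_launches
disease
malaria            165.75              0.098
placental malaria   75.12              0.050
Zika                74.05              0.222
Nipah               74.05              0.222
shigellosis, ETEC   33.98              0.070
leishmaniasis       47.81              0.024
470.76 US$M, 0.69 expected launches
```

Reading: moving all 18 candidates through the pipeline costs an expected
US$ 470.76 million (risk-adjusted — failed candidates stop spending), and
yields 0.69 expected launches by 2031, i.e. the portfolio is more likely
than not to produce no launch at all. The two simple-vaccine candidates
(Nipah, Zika) dominate the launch outlook at 0.22 each, while the fifteen
unprecedented-vaccine candidates contribute under 0.18 combined despite
carrying ~60% of the cost — the imprint of the 5% phase-II success
assumption for unprecedented vaccines.

Longer narrative scripts live in `examples/` (baseline run, modified
scenario, sensitivity grid, synthetic portfolios); each builds its input,
runs the model and explains the numbers it prints.

## Command line

A thin CLI wraps the same library calls:

```sh
p2i fixtures --out fixtures/          # dump packaged portfolio/params/overrides
p2i run --portfolio fixtures/portfolio.csv --params fixtures/params.csv \
        --overrides fixtures/overrides.yaml --out reports/
p2i sensitivity --portfolio fixtures/portfolio.csv --params fixtures/params.csv \
        --multipliers 0.9,1.1 --out reports/
p2i synth --n 20 --seed 42 --out portfolio.csv
```

`run` writes per-disease and per-year CSV tables plus a full-precision
`results.json`; with `--overrides` it also writes a baseline-vs-scenario
comparison.

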