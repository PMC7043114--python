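"""Scenario run: replace two phase-I assumptions for unprecedented vaccines
(success probability 0.50 -> 0.70, duration 2.0 -> 1.45 years) and compare
against the baseline, disease by disease.

Only candidates of the overridden archetype move; the simple- and
complex-vaccine rows are bit-identical across the two runs.
"""

from p2i import (
    aggregate_portfolio,
    apply_overrides,
    compare_scenarios,
    evi_overrides_fixture,
    evi_portfolio_fixture,
)

portfolio = evi_portfolio_fixture()
baseline = aggregate_portfolio(portfolio)

overrides = evi_overrides_fixture()
for ov in overrides:
    print(f"override: {ov.archetype} {ov.phase} {ov.field} -> {ov.value}")

scenario = aggregate_portfolio(
    portfolio.with_params(apply_overrides(portfolio.params, overrides))
)
comparison = compare_scenarios(baseline, scenario)
print()
print(comparison.round(3))
print()
print(
    f"Total expected launches rise from {baseline.total_launches:.2f} to "
    f"{scenario.total_launches:.2f}; the higher phase-I survival also raises "
    f"risk-adjusted downstream costs, from {baseline.total_cost:.2f} to "
    f"{scenario.total_cost:.2f} US$M."
)
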