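"""Synthetic portfolios: draw a seeded portfolio with the reference
archetype/phase mix and run it through the model.

The generator exists for property testing and what-if exploration: it
reproduces the structure of the real portfolio (mix of archetypes and entry
phases over a disease pool), not any particular programme's content.
"""

from p2i import aggregate_portfolio
from p2i.synth import SynthSpec, generate_portfolio

spec = SynthSpec(n_candidates=30, seed=42)
portfolio = generate_portfolio(spec)

print(f"Drew {len(portfolio.candidates)} candidates (seed {spec.seed}):")
for c in portfolio.candidates[:6]:
    print(f"  {c.candidate_id:<22} {c.archetype:<14} {c.entry_phase}")
print("  ...")

result = aggregate_portfolio(portfolio)
print()
print(
    f"Synthetic run: {result.total_cost:.2f} US$M risk-adjusted cost, "
    f"{result.total_launches:.2f} expected launches over "
    f"{portfolio.start_year}-{portfolio.end_year}."
)
print("Re-running with the same seed reproduces the identical portfolio.")
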