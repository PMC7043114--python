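"""Multiplicative sensitivity analysis.

"10% higher" means multiplying every phase's probability of success by 1.1
(clamped at 1.0) and/or every phase's cost by 1.1; phase lengths are never
perturbed. The analysis reports one-way rows (each multiplier alone) and
the full two-way grid of combinations, with percentage deltas against the
unperturbed run. Cost perturbation is exactly linear in total cost and
leaves launch outputs untouched; a probability multiplier m scales a
candidate's launch probability by m^k (pre-clamp), k = remaining phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phases import PHASES
from .portfolio import ArchetypeParams, Portfolio, ValidationError
from .model import aggregate_portfolio


@dataclass(frozen=True)
class PerturbationSpec:
    """Multipliers applied to every phase's success probability and cost."""

    prob_multiplier: float = 1.0
    cost_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.prob_multiplier <= 0 or self.cost_multiplier <= 0:
            raise ValidationError(
                f"multipliers must be > 0, got ({self.prob_multiplier}, "
                f"{self.cost_multiplier})"
            )


def perturb_params(
    params: Mapping[str, ArchetypeParams], spec: PerturbationSpec
) -> dict[str, ArchetypeParams]:
    """Scale every probability (clamped to <= 1) and cost; lengths unchanged."""
    out: dict[str, ArchetypeParams] = {}
    for name, ap in params.items():
        out[name] = ArchetypeParams(
            archetype=ap.archetype,
            cost={p: ap.cost[p] * spec.cost_multiplier for p in PHASES},
            length=dict(ap.length),
            prob_success={
                p: min(1.0, ap.prob_success[p] * spec.prob_multiplier) for p in PHASES
            },
        )
    return out


def run_perturbed(portfolio: Portfolio, spec: PerturbationSpec):
    """Aggregate the portfolio under one perturbation."""
    return aggregate_portfolio(portfolio.with_params(perturb_params(portfolio.params, spec)))


def sensitivity_table(
    portfolio: Portfolio, multipliers: Sequence[float] = (0.9, 1.1)
) -> pd.DataFrame:
    """Baseline, one-way and all two-way perturbation rows.

    Returns a DataFrame with columns prob_multiplier, cost_multiplier,
    total_cost, cost_delta_pct, total_launches, launches_delta_pct. The
    first row is the unperturbed baseline; deltas are percentages relative
    to it. Launch columns in cost-only rows equal the baseline (deltas 0) —
    cost perturbations cannot move launch probabilities.
    """
    for m in multipliers:
        if m <= 0:
            raise ValidationError(f"multipliers must be > 0, got {m}")

    specs: list[tuple[str, PerturbationSpec]] = [("baseline", PerturbationSpec())]
    specs += [
        (f"prob x{m:g}", PerturbationSpec(prob_multiplier=m)) for m in multipliers
    ]
    specs += [
        (f"cost x{m:g}", PerturbationSpec(cost_multiplier=m)) for m in multipliers
    ]
    specs += [
        (
            f"prob x{ms:g}, cost x{mc:g}",
            PerturbationSpec(prob_multiplier=ms, cost_multiplier=mc),
        )
        for ms in multipliers
        for mc in multipliers
    ]

    rows = []
    baseline_cost = baseline_launches = None
    for label, spec in specs:
        res = run_perturbed(portfolio, spec)
        if baseline_cost is None:
            baseline_cost, baseline_launches = res.total_cost, res.total_launches
        rows.append(
            {
                "label": label,
                "prob_multiplier": spec.prob_multiplier,
                "cost_multiplier": spec.cost_multiplier,
                "total_cost": res.total_cost,
                "cost_delta_pct": _pct(res.total_cost, baseline_cost),
                "total_launches": res.total_launches,
                "launches_delta_pct": _pct(res.total_launches, baseline_launches),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def _pct(value: float, base: float) -> float:
    if base == 0:
        return 0.0
    return 100.0 * (value - base) / base
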