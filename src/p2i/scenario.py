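"""Parameter-override engine for what-if runs.

A scenario is a baseline parameter set plus a list of targeted overrides
(archetype, phase, field, value). Overrides return a modified copy; the
baseline is never mutated, and candidates whose archetype is untouched
produce bit-identical results in both runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .phases import Phase
from .portfolio import ArchetypeParams, ValidationError
from .model import ScenarioResult

_FIELDS = ("cost", "length", "prob_success")


@dataclass(frozen=True)
class ParameterOverride:
    """One targeted parameter change, in the field's native units
    (US$ millions for cost, years for length, fraction for prob_success)."""

    archetype: str
    phase: Phase
    field: str
    value: float

    def __post_init__(self) -> None:
        if not isinstance(self.phase, Phase):
            object.__setattr__(self, "phase", Phase.parse(self.phase))
        if self.field not in _FIELDS:
            raise ValidationError(
                f"override field must be one of {_FIELDS}, got {self.field!r}"
            )
        v = float(self.value)
        if self.field == "prob_success" and not 0.0 <= v <= 1.0:
            raise ValidationError(f"prob_success override must be in [0, 1], got {v}")
        if self.field == "length" and v <= 0.0:
            raise ValidationError(f"length override must be > 0, got {v}")
        if self.field == "cost" and v < 0.0:
            raise ValidationError(f"cost override must be >= 0, got {v}")
        object.__setattr__(self, "value", v)


def apply_overrides(
    params: Mapping[str, ArchetypeParams],
    overrides: Iterable[ParameterOverride],
) -> dict[str, ArchetypeParams]:
    """Apply overrides to a copy of the parameter set.

    Untouched archetypes, phases and fields are value-identical to the
    input; later overrides of the same target win (overwrite semantics,
    so applying the same list twice is idempotent).
    """
    out = dict(params)
    for ov in overrides:
        if ov.archetype not in out:
            known = sorted(out)
            raise ValidationError(
                f"override targets unknown archetype {ov.archetype!r}; known: {known}"
            )
        out[ov.archetype] = out[ov.archetype].with_field(ov.phase, ov.field, ov.value)
    return out


def compare_scenarios(baseline: ScenarioResult, scenario: ScenarioResult) -> pd.DataFrame:
    """Side-by-side per-disease comparison of two runs, with a Total row.

    Columns: cost_baseline, launches_baseline, cost_scenario,
    launches_scenario, cost_delta, launches_delta. Raises if the two runs
    cover different disease sets.
    """
    b, s = baseline.by_disease, scenario.by_disease
    if set(b.index) != set(s.index):
        raise ValidationError(
            f"disease sets differ: {sorted(b.index)} vs {sorted(s.index)}"
        )
    s = s.reindex(b.index)
    cmp = pd.DataFrame(
        {
            "cost_baseline": b["cost"],
            "launches_baseline": b["expected_launches"],
            "cost_scenario": s["cost"],
            "launches_scenario": s["expected_launches"],
        }
    )
    cmp.loc["Total"] = cmp.sum()
    cmp["cost_delta"] = cmp["cost_scenario"] - cmp["cost_baseline"]
    cmp["launches_delta"] = cmp["launches_scenario"] - cmp["launches_baseline"]
    return cmp
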