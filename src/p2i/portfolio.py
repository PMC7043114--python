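"""Domain types: archetype parameters, candidates and portfolios.

An *archetype* is a product class (e.g. simple, complex or unprecedented
vaccine) whose members share per-phase assumptions on cost (US$ millions),
cycle time (years) and probability of success (fraction in [0, 1]).
A *candidate* is a single product in development, classified into an
archetype and sitting at the start of its current phase. A *portfolio*
bundles candidates with a parameter set and a calendar horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .phases import PHASES, Phase


class ValidationError(ValueError):
    """Raised when inputs violate a model invariant (bad label, domain, schema)."""


def _check_phase_map(name: str, mapping: Mapping[Phase, float]) -> dict[Phase, float]:
    missing = [p.value for p in PHASES if p not in mapping]
    if missing:
        raise ValidationError(f"{name} is missing phases: {missing}")
    extra = [k for k in mapping if k not in PHASES]
    if extra:
        raise ValidationError(f"{name} has unknown phase keys: {extra}")
    return {p: float(mapping[p]) for p in PHASES}


@dataclass(frozen=True)
class ArchetypeParams:
    """Per-phase cost, duration and success probability for one archetype.

    Parameters
    ----------
    archetype:
        Label, e.g. ``"simple_vaccine"``; any user-defined label is allowed.
    cost:
        Phase cost in US$ millions, one entry per phase, all >= 0.
    length:
        Phase duration in years, one entry per phase, all >= 0. A zero
        length is a degenerate but permitted phase whose full risk-adjusted
        cost accrues at its start instant.
    prob_success:
        Probability that a candidate entering the phase advances to the
        next one (fraction in [0, 1]).
    """

    archetype: str
    cost: Mapping[Phase, float]
    length: Mapping[Phase, float]
    prob_success: Mapping[Phase, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cost", _check_phase_map("cost", self.cost))
        object.__setattr__(self, "length", _check_phase_map("length", self.length))
        object.__setattr__(
            self, "prob_success", _check_phase_map("prob_success", self.prob_success)
        )
        for p in PHASES:
            if self.cost[p] < 0:
                raise ValidationError(f"cost[{p}] must be >= 0, got {self.cost[p]}")
            if self.length[p] < 0:
                raise ValidationError(f"length[{p}] must be >= 0, got {self.length[p]}")
            if not 0.0 <= self.prob_success[p] <= 1.0:
                raise ValidationError(
                    f"prob_success[{p}] must be in [0, 1], got {self.prob_success[p]}"
                )

    def with_field(self, phase: Phase, field_name: str, value: float) -> "ArchetypeParams":
        """Return a copy with one (phase, field) entry replaced."""
        if field_name not in ("cost", "length", "prob_success"):
            raise ValidationError(f"unknown parameter field {field_name!r}")
        new_map = dict(getattr(self, field_name))
        new_map[phase] = float(value)
        return replace(self, **{field_name: new_map})


@dataclass(frozen=True)
class Candidate:
    """One product candidate: disease target, archetype and current phase."""

    candidate_id: str
    disease: str
    archetype: str
    entry_phase: Phase

    def __post_init__(self) -> None:
        if not isinstance(self.entry_phase, Phase):
            object.__setattr__(self, "entry_phase", Phase.parse(self.entry_phase))


@dataclass(frozen=True)
class Portfolio:
    """Candidates plus parameters plus the calendar horizon over which costs
    accrue and launches are counted.

    ``start_year`` is the calendar year at whose Jan 1 every candidate begins
    its current phase; accrual past Dec 31 of ``end_year`` is discarded.
    """

    candidates: tuple[Candidate, ...]
    params: Mapping[str, ArchetypeParams]
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidates", tuple(self.candidates))
        object.__setattr__(self, "params", dict(self.params))
        if self.start_year > self.end_year:
            raise ValidationError(
                f"start_year {self.start_year} exceeds end_year {self.end_year}"
            )
        seen: set[str] = set()
        for cand in self.candidates:
            if cand.candidate_id in seen:
                raise ValidationError(f"duplicate candidate_id {cand.candidate_id!r}")
            seen.add(cand.candidate_id)
            if cand.archetype not in self.params:
                raise ValidationError(
                    f"candidate {cand.candidate_id!r} has archetype "
                    f"{cand.archetype!r} with no parameter set"
                )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def params_for(self, candidate: Candidate) -> ArchetypeParams:
        return self.params[candidate.archetype]

    def with_params(self, params: Mapping[str, ArchetypeParams]) -> "Portfolio":
        """Same candidates and horizon, different parameter set."""
        return replace(self, params=dict(params))
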