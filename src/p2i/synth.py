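"""Seeded generator of synthetic portfolios for property testing.

Synthetic portfolios reproduce the *structure* of a real product-development
portfolio — a weighted mix of archetypes and entry phases over a pool of
disease labels — without claiming anything about any particular programme.
Defaults mirror the EVI portfolio's empirical mix (15 unprecedented / 2
simple / 1 complex; 3 preclinical / 11 phase I / 4 phase II / 0 phase III).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phases import PHASES, Phase
from .portfolio import ArchetypeParams, Candidate, Portfolio, ValidationError
from .fixtures import END_YEAR, P2I_V2_PARAMS, START_YEAR

_DEFAULT_ARCHETYPE_WEIGHTS = {"unprecedented": 15.0, "simple": 2.0, "complex": 1.0}
_DEFAULT_PHASE_WEIGHTS = {
    Phase.PRECLINICAL: 3.0,
    Phase.PHASE1: 11.0,
    Phase.PHASE2: 4.0,
    Phase.PHASE3: 0.0,
}
_DEFAULT_DISEASES = (
    "malaria",
    "placental malaria",
    "leishmaniasis",
    "shigellosis, ETEC",
    "Nipah",
    "Zika",
)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic portfolio draw."""

    n_candidates: int = 18
    archetype_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ARCHETYPE_WEIGHTS)
    )
    phase_weights: Mapping[Phase, float] = field(
        default_factory=lambda: dict(_DEFAULT_PHASE_WEIGHTS)
    )
    disease_pool: Sequence[str] = _DEFAULT_DISEASES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValidationError(f"n_candidates must be >= 1, got {self.n_candidates}")
        for name, w in {**self.archetype_weights}.items():
            if w < 0:
                raise ValidationError(f"negative archetype weight for {name!r}")
        for p, w in {**self.phase_weights}.items():
            if w < 0:
                raise ValidationError(f"negative phase weight for {p}")
        if sum(self.archetype_weights.values()) <= 0:
            raise ValidationError("archetype weights must not all be zero")
        if sum(self.phase_weights.values()) <= 0:
            raise ValidationError("phase weights must not all be zero")
        if not self.disease_pool:
            raise ValidationError("disease pool must not be empty")


def generate_portfolio(
    spec: SynthSpec,
    params: Mapping[str, ArchetypeParams] | None = None,
    start_year: int = START_YEAR,
    end_year: int = END_YEAR,
) -> Portfolio:
    """Draw a portfolio by weighted sampling; deterministic for a fixed seed.

    Candidate ids are "<disease> <k>" with k counting per disease. Archetype
    parameters default to the P2I v.2 vaccine set; pass ``params`` (e.g. from
    :func:`jitter_params`) to vary them.
    """
    if params is None:
        params = dict(P2I_V2_PARAMS)
    unknown = set(spec.archetype_weights) - set(params)
    if unknown:
        raise ValidationError(f"archetype weights reference unknown archetypes: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    archetypes = sorted(spec.archetype_weights)
    a_w = np.array([spec.archetype_weights[a] for a in archetypes], dtype=float)
    a_w /= a_w.sum()
    phases = [p for p in PHASES if p in spec.phase_weights]
    p_w = np.array([spec.phase_weights[p] for p in phases], dtype=float)
    p_w /= p_w.sum()

    counter: dict[str, int] = {}
    candidates = []
    for _ in range(spec.n_candidates):
        disease = str(rng.choice(list(spec.disease_pool)))
        archetype = archetypes[int(rng.choice(len(archetypes), p=a_w))]
        phase = phases[int(rng.choice(len(phases), p=p_w))]
        counter[disease] = counter.get(disease, 0) + 1
        candidates.append(
            Candidate(f"{disease} {counter[disease]}", disease, archetype, phase)
        )
    return Portfolio(
        candidates=tuple(candidates),
        params=dict(params),
        start_year=start_year,
        end_year=end_year,
    )


def jitter_params(
    params: Mapping[str, ArchetypeParams],
    rel: float = 0.2,
    seed: int = 0,
) -> dict[str, ArchetypeParams]:
    """Multiply every cost, length and probability by U(1-rel, 1+rel) draws,
    clamping probabilities to [0, 1]. For property tests only — the jittered
    tables are not calibrated assumptions."""
    if not 0 <= rel < 1:
        raise ValidationError(f"rel must be in [0, 1), got {rel}")
    rng = np.random.default_rng(seed)

    def _scale() -> float:
        return float(rng.uniform(1.0 - rel, 1.0 + rel))

    out: dict[str, ArchetypeParams] = {}
    for name, ap in params.items():
        out[name] = ArchetypeParams(
            archetype=ap.archetype,
            cost={p: ap.cost[p] * _scale() for p in PHASES},
            length={p: ap.length[p] * _scale() for p in PHASES},
            prob_success={p: min(1.0, ap.prob_success[p] * _scale()) for p in PHASES},
        )
    return out
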