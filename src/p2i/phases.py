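"""Development phases of the pipeline model.

The model covers four phases, from advanced preclinical work through the
pivotal phase III trial. A candidate that completes phase III counts as a
*launch*; regulatory review, manufacturing scale-up and post-marketing
studies are outside the model's scope.
"""

from __future__ import annotations

import enum
import functools


@functools.total_ordering
class Phase(enum.Enum):
    """One development phase; ordered preclinical < phase1 < phase2 < phase3."""

    PRECLINICAL = "preclinical"
    PHASE1 = "phase1"
    PHASE2 = "phase2"
    PHASE3 = "phase3"

    @property
    def index(self) -> int:
        return PHASES.index(self)

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, Phase):
            return NotImplemented
        return self.index < other.index

    def __str__(self) -> str:
        return self.value

    @classmethod
    def parse(cls, label: str) -> "Phase":
        """Parse a phase label such as ``"phase1"`` (case-insensitive)."""
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(p.value for p in cls)
            raise ValueError(f"unknown phase {label!r}; expected one of: {valid}") from None


#: All phases in pipeline order.
PHASES: tuple[Phase, ...] = (Phase.PRECLINICAL, Phase.PHASE1, Phase.PHASE2, Phase.PHASE3)


def remaining_phases(entry_phase: Phase) -> tuple[Phase, ...]:
    """Phases still ahead of a candidate, from its entry phase through phase III."""
    return PHASES[entry_phase.index:]
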