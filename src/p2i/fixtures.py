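"""Packaged reference inputs: the EVI 18-candidate portfolio, the P2I v.2
vaccine-archetype parameter set, and the canonical EVI scenario overrides.

The portfolio holds 18 anonymized vaccine candidates for six diseases of
poverty and emerging infectious diseases (malaria, placental malaria,
leishmaniasis, shigellosis/ETEC, Nipah, Zika), each classified as a simple,
complex or unprecedented vaccine and sitting at the start of its current
development phase. The parameter set gives per-phase cost (US$ millions),
cycle time (years) and probability of success for the three archetypes.
The horizon is calendar 2019 through 2031.
"""

from __future__ import annotations

from .phases import Phase
from .portfolio import ArchetypeParams, Candidate, Portfolio
from .scenario import ParameterOverride

START_YEAR = 2019
END_YEAR = 2031

_P = Phase  # shorthand for the tables below

# (candidate_id, disease, archetype, entry phase)
EVI_CANDIDATES: tuple[tuple[str, str, str, Phase], ...] = (
    ("Malaria 1", "malaria", "unprecedented", _P.PHASE2),
    ("Malaria 2", "malaria", "unprecedented", _P.PHASE1),
    ("Malaria 3", "malaria", "unprecedented", _P.PHASE1),
    ("Malaria 4", "malaria", "unprecedented", _P.PHASE2),
    ("Malaria 5", "malaria", "unprecedented", _P.PHASE2),
    ("Malaria 6", "malaria", "unprecedented", _P.PRECLINICAL),
    ("Malaria 7", "malaria", "unprecedented", _P.PRECLINICAL),
    ("Malaria 8", "placental malaria", "unprecedented", _P.PHASE1),
    ("Malaria 9", "placental malaria", "unprecedented", _P.PHASE1),
    ("Malaria 10", "malaria", "unprecedented", _P.PHASE1),
    ("Malaria 11", "placental malaria", "unprecedented", _P.PHASE1),
    ("Malaria 12", "placental malaria", "unprecedented", _P.PHASE1),
    ("Malaria 13", "placental malaria", "unprecedented", _P.PHASE1),
    ("Zika 1", "Zika", "simple", _P.PHASE1),
    ("Nipah 1", "Nipah", "simple", _P.PHASE1),
    ("Diarrheal disease 1", "shigellosis, ETEC", "complex", _P.PHASE1),
    ("Leishmaniasis 1", "leishmaniasis", "unprecedented", _P.PRECLINICAL),
    ("Leishmaniasis 2", "leishmaniasis", "unprecedented", _P.PHASE2),
)

# P2I v.2 vaccine-archetype assumptions: cost US$M, length years, success fraction.
P2I_V2_PARAMS: dict[str, ArchetypeParams] = {
    "simple": ArchetypeParams(
        archetype="simple",
        cost={_P.PRECLINICAL: 6.7, _P.PHASE1: 2.2, _P.PHASE2: 13.2, _P.PHASE3: 201.0},
        length={_P.PRECLINICAL: 3.4, _P.PHASE1: 1.6, _P.PHASE2: 2.2, _P.PHASE3: 2.3},
        prob_success={_P.PRECLINICAL: 0.41, _P.PHASE1: 0.68, _P.PHASE2: 0.46, _P.PHASE3: 0.71},
    ),
    "complex": ArchetypeParams(
        archetype="complex",
        cost={_P.PRECLINICAL: 16.6, _P.PHASE1: 2.5, _P.PHASE2: 13.9, _P.PHASE3: 223.0},
        length={_P.PRECLINICAL: 3.3, _P.PHASE1: 2.0, _P.PHASE2: 3.7, _P.PHASE3: 3.5},
        prob_success={_P.PRECLINICAL: 0.41, _P.PHASE1: 0.50, _P.PHASE2: 0.22, _P.PHASE3: 0.64},
    ),
    "unprecedented": ArchetypeParams(
        archetype="unprecedented",
        cost={_P.PRECLINICAL: 16.6, _P.PHASE1: 2.5, _P.PHASE2: 13.9, _P.PHASE3: 223.0},
        length={_P.PRECLINICAL: 3.3, _P.PHASE1: 2.0, _P.PHASE2: 3.7, _P.PHASE3: 3.5},
        prob_success={_P.PRECLINICAL: 0.41, _P.PHASE1: 0.50, _P.PHASE2: 0.05, _P.PHASE3: 0.40},
    ),
}

# EVI's own historical phase data, kept as annotations. Only the two phase-I
# entries rest on 10 data points; the rest are judged too thin (2-3 points)
# to drive the model, and the EUR cost figures are deliberately not converted
# to US$. None of these rows are applied by default.
EVI_INTERNAL_DATA: tuple[dict, ...] = (
    {"stage": "Preclinical phase duration", "n": 2, "value": 36, "units": "months",
     "archetypes": "all unprecedented"},
    {"stage": "Preclinical phase cost", "n": 3, "value": 2_483_333, "units": "EUR",
     "archetypes": "1 simple, 2 unprecedented"},
    {"stage": "Technical success phase I", "n": 10, "value": 1.00, "units": "fraction",
     "archetypes": "all unprecedented"},
    {"stage": "Phase transition success phase I", "n": 10, "value": 0.70, "units": "fraction",
     "archetypes": "all unprecedented"},
    {"stage": "Duration phase I", "n": 10, "value": 17.4, "units": "months",
     "archetypes": "all unprecedented"},
    {"stage": "Phase I cost", "n": 3, "value": 1_500_000, "units": "EUR",
     "archetypes": "all unprecedented"},
    {"stage": "Technical success phase II", "n": 2, "value": 1.00, "units": "fraction",
     "archetypes": "all unprecedented"},
    {"stage": "Phase transition success phase II", "n": 2, "value": 1.00, "units": "fraction",
     "archetypes": "all unprecedented"},
    {"stage": "Duration phase II", "n": 2, "value": 22.5, "units": "months",
     "archetypes": "all unprecedented"},
)


def evi_portfolio_fixture() -> Portfolio:
    """The 18-candidate EVI portfolio with P2I v.2 parameters, horizon 2019-2031."""
    return Portfolio(
        candidates=tuple(Candidate(*row) for row in EVI_CANDIDATES),
        params=dict(P2I_V2_PARAMS),
        start_year=START_YEAR,
        end_year=END_YEAR,
    )


def evi_overrides_fixture() -> list[ParameterOverride]:
    """The two data-backed EVI modifications for the second model run:
    phase-transition success 70% and phase-I duration 1.45 years (17.4
    months) for unprecedented vaccines."""
    return [
        ParameterOverride("unprecedented", Phase.PHASE1, "prob_success", 0.70),
        ParameterOverride("unprecedented", Phase.PHASE1, "length", 1.45),
    ]
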