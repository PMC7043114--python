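"""The deterministic pipeline engine.

For a candidate i with archetype a entering phase e_i, the model computes

* entry probability  pi_{i,p} = prod_{e_i <= q < p} s_{a,q}   (empty product = 1),
* launch probability lambda_i = prod_{p >= e_i} s_{a,p},
* risk-adjusted phase cost pi_{i,p} * C_{a,p},
* a contiguous phase timeline starting at t = 0 (Jan 1 of the start year),
  each phase occupying a half-open interval of width L_{a,p},

where s, C, L are the archetype's per-phase success probabilities, costs
(US$ millions) and durations (years). Costs accrue uniformly within each
phase at rate pi * C / L per year; calendar-year totals are the sum over
phases of rate x overlap(phase interval, year). A launch is booked in the
calendar year containing the instant phase III ends (an end time landing
exactly on a year boundary counts in the earlier year). No discounting or
inflation is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .phases import Phase, remaining_phases
from .portfolio import ArchetypeParams, Candidate, Portfolio, ValidationError

__all__ = [
    "CandidateTrajectory",
    "ScenarioResult",
    "launch_probability",
    "entry_probability",
    "risk_adjusted_phase_costs",
    "phase_timeline",
    "candidate_trajectory",
    "annual_cost_accrual",
    "launch_schedule",
    "aggregate_portfolio",
]

# Guard against float drift when a phase-III end time lands on a year boundary.
_TIME_DECIMALS = 9


def _check_archetype(candidate: Candidate, params: ArchetypeParams) -> None:
    if candidate.archetype != params.archetype:
        raise ValidationError(
            f"candidate {candidate.candidate_id!r} has archetype "
            f"{candidate.archetype!r} but parameters are for {params.archetype!r}"
        )


def launch_probability(candidate: Candidate, params: ArchetypeParams) -> float:
    """Probability the candidate clears every remaining phase through phase III."""
    _check_archetype(candidate, params)
    lam = 1.0
    for p in remaining_phases(candidate.entry_phase):
        lam *= params.prob_success[p]
    return lam


def entry_probability(candidate: Candidate, params: ArchetypeParams, phase: Phase) -> float:
    """Probability of reaching ``phase`` from the entry phase (1.0 at entry)."""
    _check_archetype(candidate, params)
    if phase < candidate.entry_phase:
        raise ValidationError(
            f"phase {phase} precedes entry phase {candidate.entry_phase} "
            f"for candidate {candidate.candidate_id!r}"
        )
    pi = 1.0
    for q in remaining_phases(candidate.entry_phase):
        if q >= phase:
            break
        pi *= params.prob_success[q]
    return pi


def risk_adjusted_phase_costs(
    candidate: Candidate, params: ArchetypeParams
) -> dict[Phase, float]:
    """Expected (probability-weighted) cost of each remaining phase."""
    return {
        p: entry_probability(candidate, params, p) * params.cost[p]
        for p in remaining_phases(candidate.entry_phase)
    }


def phase_timeline(
    candidate: Candidate, params: ArchetypeParams
) -> dict[Phase, tuple[float, float]]:
    """Half-open [start, end) intervals in years since t = 0 for each remaining phase."""
    _check_archetype(candidate, params)
    intervals: dict[Phase, tuple[float, float]] = {}
    t = 0.0
    for p in remaining_phases(candidate.entry_phase):
        end = t + params.length[p]
        intervals[p] = (t, end)
        t = end
    return intervals


@dataclass(frozen=True)
class CandidateTrajectory:
    """Everything the engine derives for one candidate."""

    candidate: Candidate
    intervals: Mapping[Phase, tuple[float, float]]
    entry_prob: Mapping[Phase, float]
    risk_adjusted_cost: Mapping[Phase, float]
    launch_time: float
    launch_probability: float

    @property
    def total_risk_adjusted_cost(self) -> float:
        return sum(self.risk_adjusted_cost.values())


def candidate_trajectory(candidate: Candidate, params: ArchetypeParams) -> CandidateTrajectory:
    intervals = phase_timeline(candidate, params)
    return CandidateTrajectory(
        candidate=candidate,
        intervals=intervals,
        entry_prob={
            p: entry_probability(candidate, params, p) for p in intervals
        },
        risk_adjusted_cost=risk_adjusted_phase_costs(candidate, params),
        launch_time=max(end for _, end in intervals.values()),
        launch_probability=launch_probability(candidate, params),
    )


def annual_cost_accrual(
    candidate: Candidate,
    params: ArchetypeParams,
    start_year: int,
    end_year: int,
) -> dict[int, float]:
    """Risk-adjusted cost accrued in each calendar year of the horizon.

    Within a phase the risk-adjusted cost accrues at the uniform rate
    pi * C / L per year; a year's accrual is the overlap-weighted sum over
    phases. A zero-length phase deposits its full risk-adjusted cost at its
    start instant, into the year containing that instant. Accrual beyond
    Dec 31 of ``end_year`` is discarded.
    """
    if start_year > end_year:
        raise ValidationError(f"start_year {start_year} exceeds end_year {end_year}")
    n_years = end_year - start_year + 1
    traj = candidate_trajectory(candidate, params)
    accrual = np.zeros(n_years)
    for p, (s, e) in traj.intervals.items():
        ra_cost = traj.risk_adjusted_cost[p]
        length = e - s
        if length > 0.0:
            rate = ra_cost / length
            k_lo = max(0, int(math.floor(s)))
            k_hi = min(n_years, int(math.ceil(e)))
            for k in range(k_lo, k_hi):
                overlap = min(e, k + 1.0) - max(s, float(k))
                if overlap > 0.0:
                    accrual[k] += rate * overlap
        else:
            # Point mass at the start instant; [k, k+1) year convention.
            k = int(math.floor(round(s, _TIME_DECIMALS)))
            if 0 <= k < n_years:
                accrual[k] += ra_cost
    return {start_year + k: float(accrual[k]) for k in range(n_years)}


def launch_schedule(
    candidate: Candidate, params: ArchetypeParams, start_year: int
) -> tuple[int, float]:
    """Calendar year of the potential launch and its probability.

    The launch instant is the end of the phase-III interval; it is booked in
    the calendar year containing it, with an end time landing exactly on a
    Jan 1 boundary counted in the earlier year.
    """
    traj = candidate_trajectory(candidate, params)
    t = round(traj.launch_time, _TIME_DECIMALS)
    year = start_year if t <= 0.0 else start_year + int(math.ceil(t)) - 1
    return year, traj.launch_probability


@dataclass(frozen=True)
class ScenarioResult:
    """Aggregated portfolio outputs for one model run.

    ``by_disease`` has one row per disease (first-appearance order) with
    columns ``cost`` (US$ millions accrued within the horizon) and
    ``expected_launches``; ``schedule`` has one row per calendar year with
    ``cost_accrued``, ``cost_cumulative`` and ``launch_probability_cumulative``.
    """

    by_disease: pd.DataFrame
    schedule: pd.DataFrame

    @property
    def total_cost(self) -> float:
        return float(self.by_disease["cost"].sum())

    @property
    def total_launches(self) -> float:
        return float(self.by_disease["expected_launches"].sum())


def aggregate_portfolio(portfolio: Portfolio) -> ScenarioResult:
    """Run every candidate through the engine and aggregate by disease and year.

    Expected launches count a candidate only if its launch year falls inside
    the horizon, so the per-disease totals equal the final value of the
    cumulative annual launch series. An empty portfolio yields an all-zero
    schedule and an empty disease table.
    """
    years = list(portfolio.years)
    cost_by_year = {y: 0.0 for y in years}
    launch_by_year = {y: 0.0 for y in years}
    diseases: list[str] = []
    disease_cost: dict[str, float] = {}
    disease_launch: dict[str, float] = {}

    for cand in portfolio.candidates:
        params = portfolio.params_for(cand)
        if cand.disease not in disease_cost:
            diseases.append(cand.disease)
            disease_cost[cand.disease] = 0.0
            disease_launch[cand.disease] = 0.0
        accrual = annual_cost_accrual(cand, params, portfolio.start_year, portfolio.end_year)
        for y, c in accrual.items():
            cost_by_year[y] += c
        disease_cost[cand.disease] += sum(accrual.values())
        launch_year, lam = launch_schedule(cand, params, portfolio.start_year)
        if launch_year <= portfolio.end_year:
            launch_by_year[launch_year] += lam
            disease_launch[cand.disease] += lam

    schedule = pd.DataFrame(
        {
            "cost_accrued": [cost_by_year[y] for y in years],
            "launch_probability": [launch_by_year[y] for y in years],
        },
        index=pd.Index(years, name="year"),
    )
    schedule["cost_cumulative"] = schedule["cost_accrued"].cumsum()
    schedule["launch_probability_cumulative"] = schedule["launch_probability"].cumsum()
    schedule = schedule[
        ["cost_accrued", "cost_cumulative", "launch_probability_cumulative"]
    ]

    by_disease = pd.DataFrame(
        {
            "cost": [disease_cost[d] for d in diseases],
            "expected_launches": [disease_launch[d] for d in diseases],
        },
        index=pd.Index(diseases, name="disease"),
    )
    return ScenarioResult(by_disease=by_disease, schedule=schedule)
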