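"""CSV/YAML/JSON readers and writers.

File schemas
------------
Portfolio CSV: header ``candidate_id,disease,archetype,entry_phase`` with
``entry_phase`` one of preclinical/phase1/phase2/phase3.

Parameter CSV: header ``archetype,phase,cost_musd,length_years,prob_success``
with exactly four phase rows per archetype. Probabilities may be written as
fractions (``0.5``), percent with a trailing ``%`` (``50%``), or bare percent
(``50``); by default values with a ``%`` suffix or greater than 1 are read as
percent, and the ``percent`` flag forces either interpretation.

Overrides file: YAML or JSON list of ``{archetype, phase, field, value}``.

Reports: CSV mirrors of the per-disease, per-year, comparison and
sensitivity tables (rounded for reading: costs to 2 decimals, launch
probabilities to 3) plus ``results.json`` at full precision; rounding is a
pure rendering step and never feeds back into computation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .phases import PHASES, Phase
from .portfolio import ArchetypeParams, Candidate, ValidationError
from .model import ScenarioResult
from .scenario import ParameterOverride

logger = logging.getLogger("p2i")

PORTFOLIO_COLUMNS = ["candidate_id", "disease", "archetype", "entry_phase"]
PARAMS_COLUMNS = ["archetype", "phase", "cost_musd", "length_years", "prob_success"]


def read_portfolio(path: str | Path) -> list[Candidate]:
    """Read candidates from CSV, preserving row order."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PORTFOLIO_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"portfolio file {path} is missing columns: {missing}")
    if df.empty:
        logger.warning("portfolio file %s contains no candidates", path)
        return []
    candidates: list[Candidate] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        try:
            phase = Phase.parse(row["entry_phase"])
        except ValueError as exc:
            raise ValidationError(f"row {i + 1} of {path}: {exc}") from None
        cid = str(row["candidate_id"]).strip()
        if cid in seen:
            raise ValidationError(f"row {i + 1} of {path}: duplicate candidate_id {cid!r}")
        seen.add(cid)
        candidates.append(
            Candidate(cid, str(row["disease"]).strip(), str(row["archetype"]).strip(), phase)
        )
    return candidates


def _parse_prob(raw: object, percent: bool | None) -> float:
    s = str(raw).strip()
    if s.endswith("%"):
        value = float(s[:-1]) / 100.0
    else:
        value = float(s)
        if percent is True or (percent is None and value > 1.0):
            value /= 100.0
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"probability {raw!r} is outside [0, 100%]")
    return value


def read_params(path: str | Path, percent: bool | None = None) -> dict[str, ArchetypeParams]:
    """Read archetype parameters from CSV; four phase rows per archetype required."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PARAMS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"parameter file {path} is missing columns: {missing}")
    out: dict[str, ArchetypeParams] = {}
    for archetype, grp in df.groupby("archetype", sort=False):
        cost: dict[Phase, float] = {}
        length: dict[Phase, float] = {}
        prob: dict[Phase, float] = {}
        for i, row in grp.iterrows():
            try:
                phase = Phase.parse(row["phase"])
            except ValueError as exc:
                raise ValidationError(f"row {i + 1} of {path}: {exc}") from None
            if phase in cost:
                raise ValidationError(
                    f"archetype {archetype!r} has duplicate rows for phase {phase}"
                )
            cost[phase] = float(row["cost_musd"])
            length[phase] = float(row["length_years"])
            prob[phase] = _parse_prob(row["prob_success"], percent)
        absent = [p.value for p in PHASES if p not in cost]
        if absent:
            raise ValidationError(f"archetype {archetype!r} is missing phases: {absent}")
        out[str(archetype)] = ArchetypeParams(str(archetype), cost, length, prob)
    if not out:
        raise ValidationError(f"parameter file {path} defines no archetypes")
    return out


def read_overrides(path: str | Path) -> list[ParameterOverride]:
    """Read a YAML/JSON list of parameter overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return []
    if not isinstance(data, list):
        raise ValidationError(f"overrides file {path} must contain a list")
    out = []
    for i, item in enumerate(data):
        try:
            out.append(
                ParameterOverride(
                    archetype=str(item["archetype"]),
                    phase=Phase.parse(item["phase"]),
                    field=str(item["field"]),
                    value=float(item["value"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"entry {i} of {path}: {exc}") from None
    return out


def write_portfolio(candidates: Iterable[Candidate], path: str | Path) -> None:
    pd.DataFrame(
        [
            [c.candidate_id, c.disease, c.archetype, c.entry_phase.value]
            for c in candidates
        ],
        columns=PORTFOLIO_COLUMNS,
    ).to_csv(path, index=False)


def write_params(params: Mapping[str, ArchetypeParams], path: str | Path) -> None:
    rows = [
        [name, p.value, ap.cost[p], ap.length[p], ap.prob_success[p]]
        for name, ap in params.items()
        for p in PHASES
    ]
    pd.DataFrame(rows, columns=PARAMS_COLUMNS).to_csv(path, index=False)


def write_overrides(overrides: Iterable[ParameterOverride], path: str | Path) -> None:
    data = [
        {"archetype": o.archetype, "phase": o.phase.value, "field": o.field, "value": o.value}
        for o in overrides
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _round_disease_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].round(2 if "cost" in col else 3)
    return out


def write_reports(
    result: ScenarioResult,
    out_dir: str | Path,
    comparison: pd.DataFrame | None = None,
    sensitivity: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write rounded CSV report tables plus a full-precision results.json.

    Always writes ``by_disease.csv`` (per-disease cost and expected
    launches, with a Total row) and ``annual_schedule.csv`` (per-year
    accrual, cumulative cost and cumulative launch probability); optionally
    ``comparison.csv`` and ``sensitivity.csv``. Returns the written paths.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory {out} is not writable: {exc}") from None

    paths: dict[str, Path] = {}

    by_disease = result.by_disease.copy()
    by_disease.loc["Total"] = by_disease.sum()
    paths["by_disease"] = out / "by_disease.csv"
    _round_disease_table(by_disease).to_csv(paths["by_disease"])

    schedule = result.schedule.copy()
    schedule["cost_accrued"] = schedule["cost_accrued"].round(2)
    schedule["cost_cumulative"] = schedule["cost_cumulative"].round(2)
    schedule["launch_probability_cumulative"] = schedule[
        "launch_probability_cumulative"
    ].round(3)
    paths["annual_schedule"] = out / "annual_schedule.csv"
    schedule.to_csv(paths["annual_schedule"])

    if comparison is not None:
        paths["comparison"] = out / "comparison.csv"
        _round_disease_table(comparison).to_csv(paths["comparison"])
    if sensitivity is not None:
        sens = sensitivity.copy()
        sens["total_cost"] = sens["total_cost"].round(2)
        sens["cost_delta_pct"] = sens["cost_delta_pct"].round(2)
        sens["total_launches"] = sens["total_launches"].round(3)
        sens["launches_delta_pct"] = sens["launches_delta_pct"].round(1)
        paths["sensitivity"] = out / "sensitivity.csv"
        sens.to_csv(paths["sensitivity"])

    payload: dict = {
        "by_disease": {
            d: {
                "cost": float(result.by_disease.loc[d, "cost"]),
                "expected_launches": float(result.by_disease.loc[d, "expected_launches"]),
            }
            for d in result.by_disease.index
        },
        "total_cost": result.total_cost,
        "total_launches": result.total_launches,
        "schedule": {
            str(y): {
                "cost_accrued": float(result.schedule.loc[y, "cost_accrued"]),
                "cost_cumulative": float(result.schedule.loc[y, "cost_cumulative"]),
                "launch_probability_cumulative": float(
                    result.schedule.loc[y, "launch_probability_cumulative"]
                ),
            }
            for y in result.schedule.index
        },
    }
    if sensitivity is not None:
        payload["sensitivity"] = sensitivity.reset_index().to_dict(orient="records")
    paths["results"] = out / "results.json"
    with open(paths["results"], "w") as fh:
        json.dump(payload, fh, indent=2)
    return paths


def read_results(path: str | Path) -> dict:
    """Read back the full-precision machine results file (exact round-trip)."""
    with open(path) as fh:
        return json.load(fh)
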