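"""Trajectory file formats: canonical JSON, CSV export, schema.

JSON is the canonical on-disk format (versioned, validated on read);
CSV is a flat export for analysis — lossy for the nested option branches.
Weeks since treatment initiation are the only time axis stored; mapping to
calendar dates is the caller's concern.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .config import DEFAULT_CONFIG, EngineConfig
from .engine import AppliedChange, Prescription, Recommendation, replay_episode
from .instruments import AdherenceReport, ChecklistResponse, score_checklist

SCHEMA_VERSION = "1.0"


class TrajectoryError(ValueError):
    """A trajectory file failed validation; message names field and record."""


class VisitRecord(BaseModel):
    """One follow-up visit: instruments completed plus the applied change."""

    model_config = ConfigDict(frozen=True)

    checklist: ChecklistResponse
    adherence: AdherenceReport
    applied: Optional[AppliedChange] = None


class Trajectory(BaseModel):
    """A whole treatment episode for one patient."""

    model_config = ConfigDict(frozen=True)

    schema_version: str = SCHEMA_VERSION
    patient_id: str
    initial_prescription: Prescription
    baseline: ChecklistResponse
    visits: tuple[VisitRecord, ...] = ()
    #: Simulator ground-truth label; absent for observed data.
    latent_class: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Trajectory":
        if self.schema_version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise ValueError(
                f"unsupported schema_version {self.schema_version!r}; "
                f"this reader understands {SCHEMA_VERSION}"
            )
        if self.baseline.visit_week != 0:
            raise ValueError("baseline.visit_week must be 0")
        prev = 0.0
        for i, visit in enumerate(self.visits):
            if visit.checklist.visit_week <= prev:
                raise ValueError(
                    f"visits[{i}].checklist.visit_week={visit.checklist.visit_week} "
                    f"is not strictly after week {prev}"
                )
            prev = visit.checklist.visit_week
        return self

    def replay(self, config: EngineConfig = DEFAULT_CONFIG) -> list[Recommendation]:
        """Run the decision engine over every follow-up visit."""
        return replay_episode(
            self.baseline,
            [(v.checklist, v.adherence, v.applied) for v in self.visits],
            self.initial_prescription,
            config,
        )


def canonical_json(model: BaseModel) -> str:
    """Byte-stable serialization: sorted keys, fixed separators, newline."""
    payload = model.model_dump(mode="json")
    return json.dumps(payload, sort_keys=True, indent=2, ensure_ascii=True) + "\n"


def read_trajectory(path: str | Path) -> Trajectory:
    """Read and validate one trajectory JSON file."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TrajectoryError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return Trajectory.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise TrajectoryError(f"{path}: invalid trajectory at {loc}: {first['msg']}") from exc


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write one trajectory in canonical form (round-trip stable)."""
    Path(path).write_text(canonical_json(trajectory))


def read_cohort(path: str | Path) -> list[Trajectory]:
    """Read a JSON file holding a list of trajectories (or a single one)."""
    raw = json.loads(Path(path).read_text())
    items = raw if isinstance(raw, list) else [raw]
    out = []
    for i, item in enumerate(items):
        try:
            out.append(Trajectory.model_validate(item))
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"])
            raise TrajectoryError(
                f"{path}: trajectory {i}: invalid at {loc}: {first['msg']}"
            ) from exc
    return out


def write_cohort(cohort: Sequence[Trajectory], path: str | Path) -> None:
    payload = [t.model_dump(mode="json") for t in cohort]
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=2, ensure_ascii=True) + "\n"
    )


def _encode_options(rec: Recommendation) -> str:
    """Flatten option branches: actions joined by '+', branches by ' | '."""
    return " | ".join(
        "+".join(action.kind.value for action in branch) for branch in rec.options
    )


CSV_COLUMNS = [
    "patient_id",
    "week",
    "total",
    "use_2wk",
    "days_missed",
    "over_taking",
    "category",
    "cdp_index",
    "options",
    "alerts",
    "referral_mandatory",
    "next_visit_weeks",
]


def export_visits_csv(
    trajectories: Sequence[Trajectory],
    path: Optional[str | Path] = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One row per follow-up visit, with the engine's evaluation attached.

    Returns the table as a DataFrame and, when ``path`` is given, writes it
    as CSV. An empty cohort yields a header-only table.
    """
    rows = []
    for trajectory in trajectories:
        recs = trajectory.replay(config)
        for visit, rec in zip(trajectory.visits, recs):
            score = score_checklist(visit.checklist)
            rows.append(
                {
                    "patient_id": trajectory.patient_id,
                    "week": visit.checklist.visit_week,
                    "total": score.total,
                    "use_2wk": score.opioid_use_past_2wk,
                    "days_missed": visit.adherence.days_missed_past_week,
                    "over_taking": visit.adherence.took_more_than_prescribed,
                    "category": rec.category.value,
                    "cdp_index": rec.cdp_index,
                    "options": _encode_options(rec),
                    "alerts": ";".join(a.value for a in rec.alerts),
                    "referral_mandatory": rec.referral_mandatory,
                    "next_visit_weeks": rec.next_visit_weeks,
                }
            )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def trajectory_json_schema() -> dict:
    """JSON Schema for the trajectory file format (derived from the models)."""
    return Trajectory.model_json_schema()
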