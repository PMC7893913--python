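"""Scoring of the three patient-reported instruments.

Three instruments drive the measurement-based-care workflow:

* **TAPS** (Tobacco, Alcohol, Prescription medication, and other Substance
  use tool) — the universal screen. Only the opioid gate is applied here:
  any score above zero on the heroin or prescription-opioid item flags the
  patient for further OUD assessment. TAPS internal scoring is published
  elsewhere and is consumed as given, not reimplemented.
* **OUD Symptom Checklist** — eleven yes/no items, one per DSM-5 OUD
  criterion, plus a past-2-week opioid-use item (use of any opioid other
  than buprenorphine). Each "yes" scores one point; the total (0-11) is the
  tracked symptom score. The use item is never counted in the total.
* **PAQ-OUD** (Patient Adherence Questionnaire for OUD medication) — days
  of missed buprenorphine in the past week, an over-taking flag, and up to
  eleven endorsed reasons for non-adherence. Taking medication at least 80%
  of the time — missing no more than one day in the past week — counts as
  adherent, provided the patient is not taking more than prescribed.

Missing or malformed responses are rejected, never imputed: these scores
drive treatment decisions and silent imputation is unsafe.
"""

from __future__ import annotations

import enum
from typing import Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .config import DEFAULT_CONFIG, EngineConfig

N_CHECKLIST_ITEMS = 11

#: Machine identifiers for the 11 PAQ-OUD non-adherence reasons. The count
#: is normative; wordings are configurable display text, not contract.
REASON_CODES = (
    "side_effects",
    "cost",
    "craving",
    "withdrawal",
    "forgot",
    "felt_better",
    "felt_worse",
    "ran_out",
    "stigma",
    "dosing_inconvenient",
    "other",
)

#: Reasons that suggest the current dose is pharmacologically insufficient.
DOSE_HINT_REASONS = frozenset({"craving", "withdrawal"})


class TapsWindow(str, enum.Enum):
    past_12mo = "past_12mo"
    past_3mo = "past_3mo"


class TapsResult(BaseModel):
    """Per-substance TAPS risk scores for one administration.

    ``heroin`` and ``rx_opioid`` keys must always be present (0 when not
    endorsed); their absence signals a malformed record rather than a
    negative screen.
    """

    model_config = ConfigDict(frozen=True)

    substance_scores: Mapping[str, int]
    assessment_window: TapsWindow = TapsWindow.past_12mo

    @field_validator("substance_scores")
    @classmethod
    def _check_scores(cls, v: Mapping[str, int]) -> Mapping[str, int]:
        for substance, score in v.items():
            if score < 0:
                raise ValueError(f"negative TAPS score for {substance!r}")
        for required in ("heroin", "rx_opioid"):
            if required not in v:
                raise ValueError(
                    f"TAPS record is missing the {required!r} score; "
                    "opioid items must be present (0 if not endorsed)"
                )
        return dict(v)


class ChecklistResponse(BaseModel):
    """One administration of the OUD Symptom Checklist.

    ``items`` holds exactly 11 yes/no responses, one per DSM-5 OUD
    criterion; ``opioid_use_past_2wk`` is the supplementary use item.
    """

    model_config = ConfigDict(frozen=True)

    items: tuple[bool, ...]
    opioid_use_past_2wk: bool
    visit_week: float = Field(ge=0)

    @field_validator("items")
    @classmethod
    def _check_items(cls, v: tuple[bool, ...]) -> tuple[bool, ...]:
        if len(v) != N_CHECKLIST_ITEMS:
            raise ValueError(
                f"checklist requires exactly {N_CHECKLIST_ITEMS} items, got {len(v)}"
            )
        return v


class ChecklistScore(BaseModel):
    """Scored checklist: symptom total 0-11 plus the pass-through use flag."""

    model_config = ConfigDict(frozen=True)

    total: int = Field(ge=0, le=N_CHECKLIST_ITEMS)
    opioid_use_past_2wk: bool


class AdherenceReport(BaseModel):
    """Raw PAQ-OUD answers for one visit."""

    model_config = ConfigDict(frozen=True)

    days_missed_past_week: int = Field(ge=0, le=7)
    took_more_than_prescribed: bool = False
    reasons: frozenset[str] = frozenset()

    @field_validator("reasons")
    @classmethod
    def _check_reasons(cls, v: frozenset[str]) -> frozenset[str]:
        unknown = v - set(REASON_CODES)
        if unknown:
            raise ValueError(f"unknown non-adherence reason codes: {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _reasons_require_nonadherence(self) -> "AdherenceReport":
        some_nonadherence = self.days_missed_past_week > 0 or self.took_more_than_prescribed
        if self.reasons and not some_nonadherence:
            raise ValueError("reasons endorsed without any reported non-adherence")
        return self


class AdherenceLevel(str, enum.Enum):
    adherent = "adherent"
    nonadherent_under = "nonadherent_under"
    nonadherent_over = "nonadherent_over"


class AdherenceStatus(BaseModel):
    """Classified adherence plus the craving/withdrawal dose-increase hint."""

    model_config = ConfigDict(frozen=True)

    status: AdherenceLevel
    dose_increase_hint: bool = False

    @model_validator(mode="after")
    def _hint_requires_nonadherence(self) -> "AdherenceStatus":
        if self.dose_increase_hint and self.status is AdherenceLevel.adherent:
            raise ValueError("dose_increase_hint requires non-adherence")
        return self

    @property
    def is_adherent(self) -> bool:
        return self.status is AdherenceLevel.adherent


def taps_opioid_gate(taps: TapsResult) -> bool:
    """Return True when the TAPS screen warrants further OUD assessment.

    The gate fires on any score above zero for heroin or prescription
    opioids; scores for other substances never affect the result.
    """
    scores = taps.substance_scores
    return scores["heroin"] > 0 or scores["rx_opioid"] > 0


def score_checklist(resp: ChecklistResponse) -> ChecklistScore:
    """Sum the yes responses; the use flag passes through uncounted."""
    return ChecklistScore(
        total=sum(resp.items),
        opioid_use_past_2wk=resp.opioid_use_past_2wk,
    )


def classify_adherence(
    report: AdherenceReport, config: EngineConfig = DEFAULT_CONFIG
) -> AdherenceStatus:
    """Classify a PAQ-OUD report as adherent / under-taking / over-taking.

    Adherent means missing no more than ``config.adherent_max_missed_days``
    days (default 1, i.e. taking medication at least 80% of the time) AND
    not taking more than prescribed. When both over- and under-taking are
    reported, over-taking takes precedence so the more safety-relevant
    status surfaces; both facts remain on the report. A dose-increase hint
    is set when a non-adherent patient attributes the lapse to ongoing
    craving or opioid withdrawal.
    """
    if report.took_more_than_prescribed:
        status = AdherenceLevel.nonadherent_over
    elif report.days_missed_past_week > config.adherent_max_missed_days:
        status = AdherenceLevel.nonadherent_under
    else:
        status = AdherenceLevel.adherent
    hint = status is not AdherenceLevel.adherent and bool(
        report.reasons & DOSE_HINT_REASONS
    )
    return AdherenceStatus(status=status, dose_increase_hint=hint)


def checklist_from_row(
    items: Sequence[int], use_2wk: bool | int, visit_week: float
) -> ChecklistResponse:
    """Build a :class:`ChecklistResponse` from 0/1 CSV-style values."""
    return ChecklistResponse(
        items=tuple(bool(int(i)) for i in items),
        opioid_use_past_2wk=bool(int(use_2wk)),
        visit_week=visit_week,
    )
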