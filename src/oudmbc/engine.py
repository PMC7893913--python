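"""Longitudinal clinical decision support state machine.

The engine schedules critical decision points (CDPs) every 2 weeks from
treatment initiation (week 0, CDP #1) through week 12 (CDP #7), classifies
each follow-up visit's treatment response, and emits the matching row of
the decision-support rules table as an ordered set of alternative treatment
plans. It is decision *support*, not an autopilot: branches are offered in
printed order and the clinician's actual choice is read back from the
trajectory record, never auto-applied.

Key behaviors:

* **Adherence first.** A non-adherent visit yields a non-adherence alert
  and the single option of exploring and addressing the non-adherence
  before any dose or frequency change; when the patient attributes the
  lapse to craving or withdrawal, a consider-dose-increase alert is added.
  The response is still classified and the full-response streak updated.
* **Dose ceiling.** No recommended buprenorphine dose ever exceeds 24
  mg/day; dose-increase branches are suggested at the configured increment,
  capped at the ceiling, and dropped entirely once the patient is already
  at or above it (remaining branches keep their printed order).
* **Continuation phase.** Full response sustained for at least 4 weeks
  redirects to a single enter-continuation option and a 4-week revisit
  interval; otherwise acute-phase visits recur every 2 weeks.
* **Escalation.** Minimal/nonresponse at weeks 10-12 makes referral to
  specialty care mandatory (dose continued until specialist evaluation).
  A trial-cap alert flags minimal/nonresponse trials beyond 8 weeks and
  partial-response trials beyond 12 weeks.

Off-schedule visits map to the floor CDP — the latest scheduled week not
after the elapsed time — because escalation rules key on treatment time
already completed; beyond week 12 the week-12 rules persist.
"""

from __future__ import annotations

import enum
import logging
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, computed_field, model_validator

from .config import DEFAULT_CONFIG, EngineConfig
from .instruments import (
    AdherenceReport,
    AdherenceStatus,
    ChecklistResponse,
    ChecklistScore,
    classify_adherence,
    score_checklist,
)
from .response import ResponseCategory, classify_response

logger = logging.getLogger("oudmbc.engine")


class EpisodeStateError(RuntimeError):
    """Raised when an operation is applied in an incompatible episode phase."""


class Frequency(str, enum.Enum):
    once_daily = "once_daily"
    twice_daily = "twice_daily"


class Phase(str, enum.Enum):
    acute = "acute"
    continuation = "continuation"
    referred = "referred"


class ActionKind(str, enum.Enum):
    initiate_treatment = "initiate_treatment"
    continue_dose = "continue_dose"
    increase_dose = "increase_dose"
    split_dose_bid = "split_dose_bid"
    add_counseling = "add_counseling"
    refer_specialty = "refer_specialty"
    address_nonadherence = "address_nonadherence"
    enter_continuation = "enter_continuation"


class AlertKind(str, enum.Enum):
    nonadherence = "nonadherence"
    consider_dose_increase_for_craving_withdrawal = (
        "consider_dose_increase_for_craving_withdrawal"
    )
    minimal_response_trial_cap = "minimal_response_trial_cap"
    partial_response_trial_cap = "partial_response_trial_cap"
    relapse = "relapse"


class Prescription(BaseModel):
    """Current buprenorphine prescription (buprenorphine component only)."""

    model_config = ConfigDict(frozen=True)

    total_daily_dose_mg: float = Field(gt=0)
    frequency: Frequency = Frequency.once_daily


class Action(BaseModel):
    """One recommended action; ``detail`` carries structured payload
    such as the capped target dose of an increase."""

    model_config = ConfigDict(frozen=True)

    kind: ActionKind
    detail: Optional[dict] = None


class Recommendation(BaseModel):
    """Engine output for one visit.

    ``options`` is an ordered list of alternative plans; each inner list is
    one "OR" branch whose actions are taken together. ``fired_rule`` names
    the rules-table row that produced the output.
    """

    model_config = ConfigDict(frozen=True)

    cdp_index: int = Field(ge=1, le=7)
    category: ResponseCategory
    options: tuple[tuple[Action, ...], ...]
    alerts: tuple[AlertKind, ...] = ()
    referral_mandatory: bool = False
    next_visit_weeks: int
    fired_rule: str


class EpisodeState(BaseModel):
    """Longitudinal treatment-episode state threaded between visits."""

    model_config = ConfigDict(frozen=True)

    baseline_total: int = Field(ge=1, le=11)
    weeks_since_init: float = Field(ge=0)
    phase: Phase = Phase.acute
    prescription: Prescription
    #: Week at which the current uninterrupted run of full responses began;
    #: None when the latest classified visit was not a full response.
    full_since_week: Optional[float] = None
    last_cdp_index: int = Field(default=1, ge=1, le=7)

    @computed_field  # type: ignore[prop-decorator]
    @property
    def full_response_streak_weeks(self) -> float:
        if self.full_since_week is None:
            return 0.0
        return self.weeks_since_init - self.full_since_week

    @model_validator(mode="after")
    def _check(self) -> "EpisodeState":
        if self.full_since_week is not None and self.full_since_week > self.weeks_since_init:
            raise ValueError("full_since_week cannot be in the future")
        return self


class AppliedChange(BaseModel):
    """The clinician's (or simulator's) actual choice recorded after a visit."""

    model_config = ConfigDict(frozen=True)

    new_total_daily_dose_mg: Optional[float] = Field(default=None, gt=0)
    new_frequency: Optional[Frequency] = None
    entered_continuation: bool = False


@lru_cache(maxsize=None)
def load_rules_table() -> dict:
    """Load the shipped machine-readable rules table."""
    text = resources.files("oudmbc.data").joinpath("rules_table.yaml").read_text()
    table = yaml.safe_load(text)
    cdps = table["decision_points"]
    if sorted(cdps) != list(range(1, 8)):
        raise ValueError("rules table must define decision points 1..7")
    return table


def cdp_schedule(config: EngineConfig = DEFAULT_CONFIG) -> list[int]:
    """Scheduled acute-phase assessment weeks (0, 2, ..., 12)."""
    return list(range(0, config.max_acute_week + 1, config.acute_interval_weeks))


def map_week_to_cdp(weeks_since_init: float, config: EngineConfig = DEFAULT_CONFIG) -> int:
    """Index (1-7) of the latest scheduled CDP week at or before the visit.

    Beyond the final scheduled week the last index persists, so week-12
    rules govern all later acute-phase visits.
    """
    if weeks_since_init < 0:
        raise ValueError(f"weeks_since_init must be >= 0, got {weeks_since_init}")
    schedule = cdp_schedule(config)
    idx = sum(1 for w in schedule if w <= weeks_since_init)
    return max(1, min(idx, len(schedule)))


def apply_dose_cap(proposed_mg: float, config: EngineConfig = DEFAULT_CONFIG) -> float:
    """Cap a proposed total daily dose at the configured ceiling (24 mg)."""
    if proposed_mg <= 0:
        raise ValueError(f"proposed dose must be positive, got {proposed_mg}")
    return min(proposed_mg, config.dose_cap_mg)


def schedule_next_visit(state: EpisodeState, config: EngineConfig = DEFAULT_CONFIG) -> int:
    """Weeks until the next scheduled visit: 2 in acute, 4 in continuation."""
    if state.phase is Phase.acute:
        return config.acute_interval_weeks
    if state.phase is Phase.continuation:
        return config.continuation_interval_weeks
    raise EpisodeStateError(
        "episode has been referred to specialty care; no further visits are "
        "scheduled by this engine"
    )


def _expand_branch(
    branch: Sequence[str],
    prescription: Prescription,
    config: EngineConfig,
) -> Optional[tuple[Action, ...]]:
    """Materialize one rules-table branch against the current prescription.

    Returns None when the branch must be dropped (a dose increase while the
    patient is already at or above the ceiling).
    """
    actions: list[Action] = []
    for name in branch:
        kind = ActionKind(name)
        if kind is ActionKind.increase_dose:
            if prescription.total_daily_dose_mg >= config.dose_cap_mg:
                return None
            target = apply_dose_cap(
                prescription.total_daily_dose_mg + config.dose_increment_mg, config
            )
            actions.append(
                Action(kind=kind, detail={"target_total_daily_dose_mg": target})
            )
        elif kind is ActionKind.split_dose_bid:
            # total daily dose is unchanged by construction; only the
            # frequency moves, so no dose number is emitted here.
            detail = {"frequency": Frequency.twice_daily.value}
            if prescription.frequency is Frequency.twice_daily:
                detail["warning"] = "already dosing twice daily; split is a no-op"
            actions.append(Action(kind=kind, detail=detail))
        else:
            actions.append(Action(kind=kind))
    return tuple(actions)


_CATEGORY_ROW = {
    ResponseCategory.full: "full",
    ResponseCategory.partial: "partial",
    ResponseCategory.minimal_nonresponse: "minimal_nonresponse",
}


def evaluate_visit(
    state: EpisodeState,
    checklist: ChecklistScore,
    adherence: AdherenceStatus,
    config: EngineConfig = DEFAULT_CONFIG,
) -> tuple[Recommendation, EpisodeState]:
    """Evaluate one acute-phase follow-up visit.

    ``state.weeks_since_init`` must already hold the week of this visit;
    the checklist and adherence report are the administrations completed at
    it. Returns the recommendation and the updated state (streak and last
    CDP advanced). Phase transitions are *not* applied here — entering
    continuation is an offered option until the trajectory records it.
    """
    if state.phase is not Phase.acute:
        raise EpisodeStateError(
            f"evaluate_visit requires an acute-phase episode, got {state.phase.value}"
        )
    week = state.weeks_since_init
    cdp = map_week_to_cdp(week, config)
    if cdp == 1:
        raise EpisodeStateError(
            "follow-up visits begin at week 2 (CDP #2); week-0 guidance is "
            "treatment initiation, not re-assessment"
        )
    category = classify_response(
        state.baseline_total, checklist.total, checklist.opioid_use_past_2wk, config
    )

    full_since = (
        (state.full_since_week if state.full_since_week is not None else week)
        if category is ResponseCategory.full
        else None
    )
    streak = week - full_since if full_since is not None else 0.0

    alerts: list[AlertKind] = []
    if (
        category is ResponseCategory.minimal_nonresponse
        and week > config.minimal_trial_cap_weeks
    ):
        alerts.append(AlertKind.minimal_response_trial_cap)
    if category is ResponseCategory.partial and week > config.partial_trial_cap_weeks:
        alerts.append(AlertKind.partial_response_trial_cap)

    row = load_rules_table()["decision_points"][cdp]["rows"][_CATEGORY_ROW[category]]
    referral_mandatory = bool(row.get("referral_mandatory", False))
    next_weeks = config.acute_interval_weeks

    if not adherence.is_adherent:
        head = [AlertKind.nonadherence]
        if adherence.dose_increase_hint:
            head.append(AlertKind.consider_dose_increase_for_craving_withdrawal)
        alerts = head + alerts
        options: tuple[tuple[Action, ...], ...] = (
            (Action(kind=ActionKind.address_nonadherence),),
        )
        referral_mandatory = False
        fired = f"CDP{cdp}/{category.value}/nonadherence"
    elif (
        category is ResponseCategory.full
        and row.get("continuation_gate", False)
        and streak >= config.continuation_streak_weeks
    ):
        options = ((Action(kind=ActionKind.enter_continuation),),)
        next_weeks = config.continuation_interval_weeks
        fired = f"CDP{cdp}/full/continuation-gate"
    else:
        expanded = [
            _expand_branch(branch, state.prescription, config)
            for branch in row["branches"]
        ]
        options = tuple(b for b in expanded if b is not None)
        fired = f"CDP{cdp}/{category.value}/branches{len(options)}"

    recommendation = Recommendation(
        cdp_index=cdp,
        category=category,
        options=options,
        alerts=tuple(alerts),
        referral_mandatory=referral_mandatory,
        next_visit_weeks=next_weeks,
        fired_rule=fired,
    )
    new_state = state.model_copy(
        update={"full_since_week": full_since, "last_cdp_index": cdp}
    )
    logger.info(
        "decision week=%s cdp=%d category=%s adherent=%s rule=%s referral=%s",
        week,
        cdp,
        category.value,
        adherence.is_adherent,
        fired,
        referral_mandatory,
    )
    return recommendation, new_state


def evaluate_continuation_visit(
    state: EpisodeState,
    checklist: ChecklistScore,
    adherence: AdherenceStatus,
    config: EngineConfig = DEFAULT_CONFIG,
) -> tuple[Recommendation, EpisodeState]:
    """Evaluate a continuation-phase visit (instruments re-administered).

    Sustained full response continues the current dose at a 4-week cadence.
    Loss of full response raises a relapse alert and returns the episode to
    clinician judgment — no automated continuation-to-acute path exists.
    """
    if state.phase is not Phase.continuation:
        raise EpisodeStateError(
            f"evaluate_continuation_visit requires continuation phase, got {state.phase.value}"
        )
    week = state.weeks_since_init
    cdp = map_week_to_cdp(week, config)
    category = classify_response(
        state.baseline_total, checklist.total, checklist.opioid_use_past_2wk, config
    )
    alerts: list[AlertKind] = []
    if not adherence.is_adherent:
        alerts.append(AlertKind.nonadherence)
        if adherence.dose_increase_hint:
            alerts.append(AlertKind.consider_dose_increase_for_craving_withdrawal)
        options: tuple[tuple[Action, ...], ...] = (
            (Action(kind=ActionKind.address_nonadherence),),
        )
        fired = f"continuation/{category.value}/nonadherence"
    elif category is ResponseCategory.full:
        options = ((Action(kind=ActionKind.continue_dose),),)
        fired = "continuation/full/continue"
    else:
        alerts.append(AlertKind.relapse)
        options = (
            (
                Action(
                    kind=ActionKind.continue_dose,
                    detail={"note": "full response lost; return to clinician judgment"},
                ),
            ),
        )
        fired = f"continuation/{category.value}/relapse"
    full_since = (
        state.full_since_week
        if category is ResponseCategory.full and state.full_since_week is not None
        else (week if category is ResponseCategory.full else None)
    )
    recommendation = Recommendation(
        cdp_index=cdp,
        category=category,
        options=options,
        alerts=tuple(alerts),
        referral_mandatory=False,
        next_visit_weeks=config.continuation_interval_weeks,
        fired_rule=fired,
    )
    new_state = state.model_copy(update={"full_since_week": full_since})
    logger.info(
        "decision week=%s phase=continuation category=%s rule=%s",
        week,
        category.value,
        fired,
    )
    return recommendation, new_state


def replay_episode(
    baseline: ChecklistResponse,
    visits: Sequence[tuple[ChecklistResponse, AdherenceReport, Optional[AppliedChange]]],
    initial_prescription: Optional[Prescription] = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[Recommendation]:
    """Drive the engine across a whole treatment trajectory.

    The week-0 record is the baseline; follow-up visits must be sorted by
    strictly increasing week. Dose changes and the continuation transition
    applied between visits are taken from the trajectory's applied-change
    log (the clinician's recorded choice), never auto-applied from the
    emitted options. Returns one recommendation per follow-up visit.
    """
    if baseline.visit_week != 0:
        raise ValueError("baseline checklist must be administered at week 0")
    baseline_score = score_checklist(baseline)
    if baseline_score.total < 1:
        raise ValueError(
            "baseline checklist total is 0: patient is not symptomatic and "
            "change-from-baseline response is undefined"
        )
    prescription = initial_prescription or Prescription(
        total_daily_dose_mg=config.initiation_dose_mg
    )
    state = EpisodeState(
        baseline_total=baseline_score.total,
        weeks_since_init=0,
        phase=Phase.acute,
        prescription=prescription,
    )
    recommendations: list[Recommendation] = []
    prev_week = 0.0
    for i, (resp, adherence_report, applied) in enumerate(visits):
        if resp.visit_week <= prev_week:
            raise ValueError(
                f"visit {i}: weeks must be strictly increasing "
                f"({resp.visit_week} after {prev_week})"
            )
        prev_week = resp.visit_week
        state = state.model_copy(update={"weeks_since_init": resp.visit_week})
        checklist = score_checklist(resp)
        adherence = classify_adherence(adherence_report, config)
        if state.phase is Phase.acute:
            rec, state = evaluate_visit(state, checklist, adherence, config)
        else:
            rec, state = evaluate_continuation_visit(state, checklist, adherence, config)
        recommendations.append(rec)
        if applied is not None:
            update: dict = {}
            rx = state.prescription
            if applied.new_total_daily_dose_mg is not None:
                rx = rx.model_copy(
                    update={"total_daily_dose_mg": applied.new_total_daily_dose_mg}
                )
            if applied.new_frequency is not None:
                rx = rx.model_copy(update={"frequency": applied.new_frequency})
            update["prescription"] = rx
            if applied.entered_continuation:
                update["phase"] = Phase.continuation
            state = state.model_copy(update=update)
    return recommendations
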