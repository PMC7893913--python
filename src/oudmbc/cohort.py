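"""Seeded synthetic patient-trajectory generator.

No real dataset exists for this workflow, so the generator produces
trajectories with the statistical structure the decision algorithm
assumes: a symptomatic baseline (checklist total 6-11 by default), one of
three latent response classes, per-class adherence lapse rates, and
optional dropout producing truncated, off-schedule trajectories.

Latent classes and the paths they follow (lapse-free defaults):

* ``full_responder`` — improves through the partial band, then crosses the
  >75%-decrease / no-use threshold at ``full_response_week`` (default week
  6) and stays there; enters the continuation phase once full response has
  been sustained 4 weeks.
* ``partial_responder`` — remains in the 25-75% decrease band (or above
  75% with ongoing use) through week 12.
* ``nonresponder`` — stays below a 25% decrease with ongoing opioid use,
  reaching mandatory specialty referral at week 10.

Item-level checklist responses are produced by sampling which endorsed
criteria remit, uniformly among the baseline-endorsed items, to hit the
target total; only the total and the use flag are normative for the
engine. The simulated clinician applies the first-listed branch of each
recommendation (printed order is the emphasis order); a choice-policy hook
can override this.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import DEFAULT_CONFIG, EngineConfig
from .engine import (
    Action,
    ActionKind,
    AppliedChange,
    EpisodeState,
    Frequency,
    Phase,
    Prescription,
    Recommendation,
    evaluate_continuation_visit,
    evaluate_visit,
)
from .instruments import (
    AdherenceReport,
    ChecklistResponse,
    classify_adherence,
    score_checklist,
)
from .io import Trajectory, VisitRecord
from .response import ResponseCategory

CLASSES = ("full_responder", "partial_responder", "nonresponder")

#: Category each latent class should show once its path has played out.
CLASS_TO_CATEGORY = {
    "full_responder": ResponseCategory.full,
    "partial_responder": ResponseCategory.partial,
    "nonresponder": ResponseCategory.minimal_nonresponse,
}

_REASON_POOLS = {
    "full_responder": ("forgot", "dosing_inconvenient", "side_effects"),
    "partial_responder": ("forgot", "cost", "side_effects", "dosing_inconvenient"),
    "nonresponder": ("craving", "withdrawal", "ran_out", "felt_worse"),
}


class CohortParams(BaseModel):
    """Generation parameters for a synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(gt=0)
    seed: int = 0
    class_probs: dict[str, float] = {
        "full_responder": 0.4,
        "partial_responder": 0.35,
        "nonresponder": 0.25,
    }
    #: Inclusive baseline checklist-total range; entrants are symptomatic.
    baseline_score_range: tuple[int, int] = (6, 11)
    #: Week by which full responders cross the full-response threshold.
    full_response_week: int = 6
    #: Per-day probability of a missed dose, by latent class.
    p_missed_day: dict[str, float] = {
        "full_responder": 0.02,
        "partial_responder": 0.05,
        "nonresponder": 0.12,
    }
    #: Per-visit probability of reporting taking more than prescribed.
    p_overtake: float = Field(default=0.02, ge=0, le=1)
    #: Per-visit probability of dropping out after the visit.
    dropout_hazard: float = Field(default=0.05, ge=0, le=1)
    #: Per-visit probability the next visit slips 1-3 weeks off schedule.
    p_visit_delay: float = Field(default=0.1, ge=0, le=1)
    #: Probability that an improving full responder still reports use at an
    #: early visit (classified partial via the >75%-with-use arm).
    p_early_use: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "CohortParams":
        if set(self.class_probs) != set(CLASSES):
            raise ValueError(f"class_probs must cover exactly {CLASSES}")
        if any(not 0 <= p <= 1 for p in self.class_probs.values()):
            raise ValueError("class probabilities must be within [0, 1]")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        lo, hi = self.baseline_score_range
        if not (1 <= lo <= hi <= 11):
            raise ValueError("baseline_score_range must lie within 1..11")
        if set(self.p_missed_day) != set(CLASSES):
            raise ValueError(f"p_missed_day must cover exactly {CLASSES}")
        return self


def _full_target(baseline: int) -> int:
    """Largest total strictly below a quarter of baseline (>75% decrease)."""
    return max(0, -(-baseline // 4) - 1)


def _minimal_target(baseline: int, rng: np.random.Generator) -> int:
    """A total above three quarters of baseline (<25% decrease)."""
    lowest = int(np.floor(0.75 * baseline)) + 1
    return int(rng.integers(lowest, baseline + 1))


def _partial_target(baseline: int, rng: np.random.Generator) -> int:
    """A total inside the inclusive 25-75% decrease band."""
    lo = -(-baseline // 4)          # ceil(b/4): decrease <= 75%
    hi = (3 * baseline) // 4        # floor(3b/4): decrease >= 25%
    return int(rng.integers(lo, hi + 1))


def _items_for_total(
    baseline_items: tuple[bool, ...], total: int, rng: np.random.Generator
) -> tuple[bool, ...]:
    """Sample which baseline-endorsed criteria remain endorsed."""
    endorsed = [i for i, yes in enumerate(baseline_items) if yes]
    keep = set(rng.choice(endorsed, size=total, replace=False)) if total else set()
    return tuple(i in keep for i in range(len(baseline_items)))


def _adherence_report(
    cls: str, params: CohortParams, rng: np.random.Generator
) -> AdherenceReport:
    days = int(rng.binomial(7, params.p_missed_day[cls]))
    over = bool(rng.random() < params.p_overtake)
    reasons: frozenset[str] = frozenset()
    if days > 0 or over:
        pool = _REASON_POOLS[cls]
        k = int(rng.integers(1, min(2, len(pool)) + 1))
        reasons = frozenset(rng.choice(pool, size=k, replace=False).tolist())
    return AdherenceReport(
        days_missed_past_week=days, took_more_than_prescribed=over, reasons=reasons
    )


#: A choice policy maps a recommendation to the branch the simulated
#: clinician follows; the default takes the first-listed branch.
ChoicePolicy = Callable[[Recommendation], Optional[tuple[Action, ...]]]


def first_branch_policy(rec: Recommendation) -> Optional[tuple[Action, ...]]:
    return rec.options[0] if rec.options else None


def _applied_from_branch(
    branch: Optional[tuple[Action, ...]], prescription: Prescription
) -> Optional[AppliedChange]:
    """Translate a chosen branch into the recorded prescription change."""
    if branch is None:
        return None
    dose: Optional[float] = None
    freq: Optional[Frequency] = None
    entered = False
    for action in branch:
        if action.kind is ActionKind.increase_dose and action.detail:
            dose = action.detail["target_total_daily_dose_mg"]
        elif action.kind is ActionKind.split_dose_bid:
            freq = Frequency.twice_daily
        elif action.kind is ActionKind.enter_continuation:
            entered = True
    if dose is None and freq is None and not entered:
        return None
    return AppliedChange(
        new_total_daily_dose_mg=dose, new_frequency=freq, entered_continuation=entered
    )


def _target_for_visit(
    cls: str,
    baseline: int,
    week: float,
    params: CohortParams,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """(checklist total, use flag) for one visit of a latent class."""
    if cls == "nonresponder":
        return _minimal_target(baseline, rng), True
    if cls == "partial_responder":
        return _partial_target(baseline, rng), False
    # full responder
    if week >= params.full_response_week:
        return _full_target(baseline), False
    if rng.random() < params.p_early_use:
        return _full_target(baseline), True  # big drop but still using: partial
    return _partial_target(baseline, rng), False


def generate_trajectory(
    patient_id: str,
    cls: str,
    params: CohortParams,
    rng: np.random.Generator,
    config: EngineConfig = DEFAULT_CONFIG,
    choice_policy: ChoicePolicy = first_branch_policy,
) -> Trajectory:
    """Simulate one patient episode, driving the engine visit by visit."""
    lo, hi = params.baseline_score_range
    baseline_total = int(rng.integers(lo, hi + 1))
    endorsed = rng.choice(11, size=baseline_total, replace=False)
    baseline_items = tuple(i in set(endorsed) for i in range(11))
    baseline = ChecklistResponse(
        items=baseline_items, opioid_use_past_2wk=True, visit_week=0
    )
    prescription = Prescription(total_daily_dose_mg=config.initiation_dose_mg)
    state = EpisodeState(
        baseline_total=baseline_total, weeks_since_init=0, prescription=prescription
    )
    visits: list[VisitRecord] = []
    week = float(config.acute_interval_weeks)
    while week <= config.max_acute_week:
        total, use = _target_for_visit(cls, baseline_total, week, params, rng)
        resp = ChecklistResponse(
            items=_items_for_total(baseline_items, total, rng),
            opioid_use_past_2wk=use,
            visit_week=week,
        )
        report = _adherence_report(cls, params, rng)
        state = state.model_copy(update={"weeks_since_init": week})
        evaluator = (
            evaluate_visit if state.phase is Phase.acute else evaluate_continuation_visit
        )
        rec, state = evaluator(state, score_checklist(resp), classify_adherence(report, config), config)
        applied = _applied_from_branch(choice_policy(rec), state.prescription)
        visits.append(VisitRecord(checklist=resp, adherence=report, applied=applied))
        if applied is not None:
            rx = state.prescription
            if applied.new_total_daily_dose_mg is not None:
                rx = rx.model_copy(
                    update={"total_daily_dose_mg": applied.new_total_daily_dose_mg}
                )
            if applied.new_frequency is not None:
                rx = rx.model_copy(update={"frequency": applied.new_frequency})
            phase = Phase.continuation if applied.entered_continuation else state.phase
            state = state.model_copy(update={"prescription": rx, "phase": phase})
        if rng.random() < params.dropout_hazard:
            break
        week += float(rec.next_visit_weeks)
        if rng.random() < params.p_visit_delay:
            week += float(rng.integers(1, 4))  # late arrival; maps to floor CDP
    return Trajectory(
        patient_id=patient_id,
        latent_class=cls,
        initial_prescription=prescription,
        baseline=baseline,
        visits=tuple(visits),
    )


def generate_cohort(
    params: CohortParams,
    config: EngineConfig = DEFAULT_CONFIG,
    choice_policy: ChoicePolicy = first_branch_policy,
) -> list[Trajectory]:
    """Generate a seeded, reproducible cohort of synthetic trajectories."""
    rng = np.random.default_rng(params.seed)
    labels = rng.choice(
        CLASSES, size=params.n_patients, p=[params.class_probs[c] for c in CLASSES]
    )
    width = max(4, len(str(params.n_patients)))
    return [
        generate_trajectory(f"P{i:0{width}d}", str(cls), params, rng, config, choice_policy)
        for i, cls in enumerate(labels, start=1)
    ]


def final_category(
    trajectory: Trajectory, config: EngineConfig = DEFAULT_CONFIG
) -> ResponseCategory:
    """Response category at the trajectory's last completed visit."""
    from .engine import replay_episode

    recs = replay_episode(
        trajectory.baseline,
        [(v.checklist, v.adherence, v.applied) for v in trajectory.visits],
        trajectory.initial_prescription,
        config,
    )
    return recs[-1].category


def class_recovery(
    cohort: list[Trajectory], config: EngineConfig = DEFAULT_CONFIG
) -> float:
    """Fraction of patients whose final classified category matches their
    latent class. With lapse-free parameters this is the simulator's
    self-consistency check."""
    hits = sum(
        1
        for t in cohort
        if t.latent_class is not None
        and final_category(t, config) is CLASS_TO_CATEGORY[t.latent_class]
    )
    return hits / len(cohort)


def worked_example_trajectory() -> Trajectory:
    """The published worked scenario as a scripted trajectory (synthetic
    checklist totals; the response bands are what is normative).

    A patient using heroin daily is stabilized on 8 mg buprenorphine at
    week 0. At week 2 use has decreased but continues, so the response is
    partial and the clinician increases the dose to 12 mg. At week 4 the
    patient reports 2 days of small use — still a partial response — and
    the dose is held. At week 6 the patient reports no use since the last
    visit and achieves full response.
    """
    baseline_items = tuple(i < 8 for i in range(11))  # total 8

    def follow_up(week: float, total: int, use: bool) -> ChecklistResponse:
        return ChecklistResponse(
            items=tuple(i < total for i in range(11)),
            opioid_use_past_2wk=use,
            visit_week=week,
        )

    ok = AdherenceReport(days_missed_past_week=0)
    return Trajectory(
        patient_id="worked-example-2",
        latent_class="full_responder",
        initial_prescription=Prescription(total_daily_dose_mg=8.0),
        baseline=ChecklistResponse(
            items=baseline_items, opioid_use_past_2wk=True, visit_week=0
        ),
        visits=(
            # >75% drop but ongoing daily use: partial; clinician increases to 12 mg
            VisitRecord(
                checklist=follow_up(2, 1, True),
                adherence=ok,
                applied=AppliedChange(new_total_daily_dose_mg=12.0),
            ),
            # 2 days of small use: still partial; dose held
            VisitRecord(checklist=follow_up(4, 1, True), adherence=ok, applied=None),
            # no use since last visit: full response
            VisitRecord(checklist=follow_up(6, 1, False), adherence=ok, applied=None),
        ),
    )
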