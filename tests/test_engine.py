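"""Decision engine: rules-table equivalence, caps, scheduling, replay.

ORACLE_TABLE below is a second, independent transcription of the published
decision-support grid (weeks 2-12 by response category), kept deliberately
separate from the YAML asset the engine loads, so the two can disagree if
either transcription drifts.
"""

import pytest
from hypothesis import given, settings, strategies as st

from oudmbc import (
    ActionKind,
    AdherenceReport,
    AlertKind,
    ChecklistResponse,
    EpisodeStateError,
    Frequency,
    Phase,
    Prescription,
    Recommendation,
    ResponseCategory,
    apply_dose_cap,
    canonical_json,
    cdp_schedule,
    classify_adherence,
    evaluate_continuation_visit,
    evaluate_visit,
    map_week_to_cdp,
    replay_episode,
    schedule_next_visit,
    score_checklist,
)
from helpers import ADHERENT, checklist, state

FULL = ResponseCategory.full
PARTIAL = ResponseCategory.partial
MINIMAL = ResponseCategory.minimal_nonresponse

I, C, UP, BID, CO, REF = (
    "initiate_treatment",
    "continue_dose",
    "increase_dose",
    "split_dose_bid",
    "add_counseling",
    "refer_specialty",
)

# (branches in printed order, referral_mandatory) per CDP x category.
# Full-response rows are the no-sustained-streak arm ("otherwise continue
# current dose"); the >=4-week streak arm is checked separately.
ORACLE_TABLE = {
    2: {
        FULL: ([[C]], False),
        PARTIAL: ([[C], [UP]], False),
        MINIMAL: ([[UP]], False),
    },
    3: {
        FULL: ([[C]], False),
        PARTIAL: ([[UP, CO], [C, CO]], False),
        MINIMAL: ([[UP, CO], [C, CO]], False),
    },
    4: {
        FULL: ([[C]], False),
        PARTIAL: ([[UP, CO], [BID, CO]], False),
        MINIMAL: ([[UP, CO], [BID, CO], [REF, C]], False),
    },
    5: {
        FULL: ([[C]], False),
        PARTIAL: ([[UP, CO], [BID, CO]], False),
        MINIMAL: ([[BID, CO], [REF, C]], False),
    },
    6: {
        FULL: ([[C]], False),
        PARTIAL: ([[UP], [CO], [REF, C]], False),
        MINIMAL: ([[REF, C]], True),
    },
    7: {
        FULL: ([[C]], False),
        PARTIAL: ([[UP], [CO], [REF, C]], False),
        MINIMAL: ([[REF, C]], True),
    },
}

# (baseline, current, use) triplets that land in each category (baseline 8).
CATEGORY_INPUTS = {FULL: (8, 1, False), PARTIAL: (8, 4, False), MINIMAL: (8, 7, False)}

NONADHERENT = AdherenceReport(days_missed_past_week=3, reasons=frozenset({"forgot"}))


def run_visit(cdp, category, dose=8.0, adherent=True, frequency=Frequency.once_daily):
    baseline, current, use = CATEGORY_INPUTS[category]
    week = 2 * (cdp - 1)
    st_ = state(week=week, baseline=baseline, dose=dose, frequency=frequency)
    score = score_checklist(checklist(current, use, week))
    report = ADHERENT if adherent else NONADHERENT
    return evaluate_visit(st_, score, classify_adherence(report))


def expected_options(branches, dose, cap=24.0, step=4.0):
    """Apply the dose ceiling to an oracle row the way a clinician would."""
    out = []
    for branch in branches:
        if UP in branch and dose >= cap:
            continue
        acts = []
        for kind in branch:
            if kind == UP:
                acts.append((kind, min(dose + step, cap)))
            else:
                acts.append((kind, None))
        out.append(acts)
    return out


def observed_options(rec: Recommendation):
    return [
        [
            (
                a.kind.value,
                a.detail.get("target_total_daily_dose_mg")
                if a.kind is ActionKind.increase_dose and a.detail
                else None,
            )
            for a in branch
        ]
        for branch in rec.options
    ]


class TestRuleTableEquivalence:
    def test_exhaustive_sweep_matches_independent_oracle(self):
        """Every (CDP, category, adherence, starting dose) cell matches the
        hand-transcribed grid, including footnote alerts and the ceiling."""
        for cdp in range(2, 8):
            for category, (branches, referral) in ORACLE_TABLE[cdp].items():
                for dose in range(2, 33, 2):
                    for adherent in (True, False):
                        rec, _ = run_visit(cdp, category, float(dose), adherent)
                        assert rec.cdp_index == cdp
                        assert rec.category is category
                        if not adherent:
                            assert rec.alerts[0] is AlertKind.nonadherence
                            assert observed_options(rec) == [[("address_nonadherence", None)]]
                            assert rec.referral_mandatory is False
                        else:
                            assert rec.referral_mandatory is referral
                            assert observed_options(rec) == expected_options(
                                branches, float(dose)
                            )
                        # footnote: minimal/nonresponse trials beyond 8 weeks
                        week = 2 * (cdp - 1)
                        expect_cap = category is MINIMAL and week > 8
                        assert (
                            AlertKind.minimal_response_trial_cap in rec.alerts
                        ) is expect_cap

    def test_no_recommended_dose_exceeds_ceiling(self):
        for cdp in range(2, 8):
            for category in (FULL, PARTIAL, MINIMAL):
                for dose in range(2, 33, 2):
                    rec, _ = run_visit(cdp, category, float(dose))
                    for branch in rec.options:
                        for action in branch:
                            if action.detail and "target_total_daily_dose_mg" in action.detail:
                                assert action.detail["target_total_daily_dose_mg"] <= 24.0

    def test_increase_branch_dropped_at_ceiling_keeps_printed_order(self):
        rec, _ = run_visit(4, MINIMAL, dose=24.0)
        assert observed_options(rec) == [
            [(BID, None), (CO, None)],
            [(REF, None), (C, None)],
        ]

    def test_partial_trial_cap_alert_beyond_week_12(self):
        st_ = state(week=13, dose=8.0)
        rec, _ = evaluate_visit(
            st_, score_checklist(checklist(4, False, 13)), classify_adherence(ADHERENT)
        )
        assert rec.cdp_index == 7
        assert AlertKind.partial_response_trial_cap in rec.alerts

    def test_nonadherence_with_craving_adds_dose_hint_alert(self):
        report = AdherenceReport(days_missed_past_week=3, reasons=frozenset({"craving"}))
        st_ = state(week=4)
        rec, _ = evaluate_visit(
            st_, score_checklist(checklist(4, False, 4)), classify_adherence(report)
        )
        assert rec.alerts[:2] == (
            AlertKind.nonadherence,
            AlertKind.consider_dose_increase_for_craving_withdrawal,
        )

    def test_bid_split_when_already_bid_is_flagged_noop(self):
        rec, _ = run_visit(4, PARTIAL, dose=24.0, frequency=Frequency.twice_daily)
        bid_action = rec.options[0][0]
        assert bid_action.kind is ActionKind.split_dose_bid
        assert "no-op" in bid_action.detail["warning"]


class TestScheduling:
    @pytest.mark.parametrize(
        ("weeks", "cdp"), [(0, 1), (2, 2), (3, 2), (5, 3), (8, 5), (12, 7), (13, 7), (40, 7)]
    )
    def test_week_maps_to_floor_cdp(self, weeks, cdp):
        assert map_week_to_cdp(weeks) == cdp

    def test_negative_weeks_rejected(self):
        with pytest.raises(ValueError):
            map_week_to_cdp(-1)

    def test_seven_biweekly_decision_points_over_twelve_weeks(self):
        assert cdp_schedule() == [0, 2, 4, 6, 8, 10, 12]

    def test_visit_cadence_by_phase(self):
        assert schedule_next_visit(state(week=2)) == 2
        continuation = state(week=10).model_copy(update={"phase": Phase.continuation})
        assert schedule_next_visit(continuation) == 4
        referred = state(week=10).model_copy(update={"phase": Phase.referred})
        with pytest.raises(EpisodeStateError):
            schedule_next_visit(referred)

    @pytest.mark.parametrize("cap_examples", [(28.0, 24.0), (16.0, 16.0), (24.0, 24.0)])
    def test_dose_cap(self, cap_examples):
        proposed, expected = cap_examples
        assert apply_dose_cap(proposed) == expected

    def test_dose_cap_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            apply_dose_cap(0)

    def test_followup_before_week_2_is_a_state_error(self):
        with pytest.raises(EpisodeStateError, match="week 2"):
            evaluate_visit(
                state(week=1), score_checklist(checklist(4, False, 1)), classify_adherence(ADHERENT)
            )

    def test_non_acute_phase_rejected(self):
        continuation = state(week=8).model_copy(update={"phase": Phase.continuation})
        with pytest.raises(EpisodeStateError):
            evaluate_visit(
                continuation,
                score_checklist(checklist(1, False, 8)),
                classify_adherence(ADHERENT),
            )


class TestContinuation:
    def test_streak_of_four_weeks_gates_continuation(self):
        """Full since week 2 -> single enter-continuation option at week 6
        with a 4-week revisit; full response only since this visit -> not yet."""
        base = checklist(8, True, 0)
        visits = [(checklist(1, False, w), ADHERENT, None) for w in (2, 4, 6)]
        recs = replay_episode(base, visits)
        assert [r.category for r in recs] == [FULL, FULL, FULL]
        assert [[a.kind for a in b] for b in recs[2].options] == [
            [ActionKind.enter_continuation]
        ]
        assert recs[2].next_visit_weeks == 4
        assert [[a.kind for a in b] for b in recs[1].options] == [
            [ActionKind.continue_dose]
        ]
        assert recs[1].next_visit_weeks == 2

    def test_streak_resets_on_losing_full_response(self):
        base = checklist(8, True, 0)
        visits = [
            (checklist(1, False, 2), ADHERENT, None),
            (checklist(4, False, 4), ADHERENT, None),  # partial: streak resets
            (checklist(1, False, 6), ADHERENT, None),
            (checklist(1, False, 8), ADHERENT, None),
        ]
        recs = replay_episode(base, visits)
        assert ActionKind.enter_continuation not in [
            a.kind for r in recs for b in r.options for a in b
        ]

    def test_continuation_visit_continue_while_full(self):
        st_ = state(week=14, full_since=6).model_copy(update={"phase": Phase.continuation})
        rec, _ = evaluate_continuation_visit(
            st_, score_checklist(checklist(1, False, 14)), classify_adherence(ADHERENT)
        )
        assert rec.category is FULL
        assert rec.next_visit_weeks == 4
        assert AlertKind.relapse not in rec.alerts

    def test_continuation_relapse_alert_on_lost_full_response(self):
        st_ = state(week=14, full_since=6).model_copy(update={"phase": Phase.continuation})
        rec, new_state = evaluate_continuation_visit(
            st_, score_checklist(checklist(5, True, 14)), classify_adherence(ADHERENT)
        )
        assert AlertKind.relapse in rec.alerts
        assert new_state.full_since_week is None


class TestReplay:
    def test_persistent_minimal_responder_referred_at_week_10(self):
        """An uninterrupted minimal responder first hits mandatory referral
        and the trial-cap alert at the week-10 visit, and never enters
        continuation."""
        base = checklist(8, True, 0)
        visits = [(checklist(8, True, w), ADHERENT, None) for w in range(2, 13, 2)]
        recs = replay_episode(base, visits)
        referral_weeks = [v[0].visit_week for v, r in zip(visits, recs) if r.referral_mandatory]
        assert referral_weeks == [10, 12]
        cap_weeks = [
            v[0].visit_week
            for v, r in zip(visits, recs)
            if AlertKind.minimal_response_trial_cap in r.alerts
        ]
        assert cap_weeks == [10, 12]
        assert all(
            ActionKind.enter_continuation not in [a.kind for b in r.options for a in b]
            for r in recs
        )

    def test_identical_visit_to_baseline_with_use_gets_increase(self):
        base = checklist(8, True, 0)
        recs = replay_episode(base, [(checklist(8, True, 2), ADHERENT, None)])
        assert recs[0].category is MINIMAL
        assert [[a.kind for a in b] for b in recs[0].options] == [
            [ActionKind.increase_dose]
        ]

    def test_non_monotone_weeks_rejected(self):
        base = checklist(8, True, 0)
        visits = [
            (checklist(4, False, 4), ADHERENT, None),
            (checklist(4, False, 2), ADHERENT, None),
        ]
        with pytest.raises(ValueError, match="strictly increasing"):
            replay_episode(base, visits)

    def test_asymptomatic_baseline_rejected(self):
        with pytest.raises(ValueError, match="not symptomatic"):
            replay_episode(checklist(0, False, 0), [])

    def test_determinism_byte_stable(self):
        rec_a, state_a = run_visit(5, MINIMAL, dose=10.0)
        rec_b, state_b = run_visit(5, MINIMAL, dose=10.0)
        assert canonical_json(rec_a) == canonical_json(rec_b)
        assert canonical_json(state_a) == canonical_json(state_b)

    def test_full_never_emitted_with_use_flag(self):
        for current in range(0, 9):
            base = checklist(8, True, 0)
            recs = replay_episode(base, [(checklist(current, True, 2), ADHERENT, None)])
            assert recs[0].category is not FULL

    @settings(deadline=None, max_examples=60)
    @given(
        cats=st.lists(st.sampled_from([FULL, PARTIAL, MINIMAL]), min_size=1, max_size=6)
    )
    def test_continuation_offered_only_after_sustained_full_response(self, cats):
        """Across random category sequences, enter-continuation appears iff
        full response has been held for at least 4 consecutive weeks."""
        totals = {FULL: 1, PARTIAL: 4, MINIMAL: 7}
        base = checklist(8, True, 0)
        weeks = [2 * (i + 1) for i in range(len(cats))]
        visits = [
            (checklist(totals[c], False, w), ADHERENT, None)
            for c, w in zip(cats, weeks)
        ]
        recs = replay_episode(base, visits)
        run_start = None
        for cat, week, rec in zip(cats, weeks, recs):
            run_start = (run_start if run_start is not None else week) if cat is FULL else None
            expected_gate = (
                cat is FULL and run_start is not None and week - run_start >= 4
            )
            offered = ActionKind.enter_continuation in [
                a.kind for b in rec.options for a in b
            ]
            assert offered is expected_gate
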