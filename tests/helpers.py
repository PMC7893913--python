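"""Shared construction helpers for the test suite."""

from __future__ import annotations

from oudmbc import (
    AdherenceReport,
    ChecklistResponse,
    EpisodeState,
    Frequency,
    Prescription,
)


def checklist(total: int, use: bool = False, week: float = 2) -> ChecklistResponse:
    """A checklist response with the first ``total`` items endorsed."""
    return ChecklistResponse(
        items=tuple(i < total for i in range(11)),
        opioid_use_past_2wk=use,
        visit_week=week,
    )


ADHERENT = AdherenceReport(days_missed_past_week=0)


def state(
    week: float = 2,
    baseline: int = 8,
    dose: float = 8.0,
    frequency: Frequency = Frequency.once_daily,
    full_since: float | None = None,
) -> EpisodeState:
    return EpisodeState(
        baseline_total=baseline,
        weeks_since_init=week,
        prescription=Prescription(total_daily_dose_mg=dose, frequency=frequency),
        full_since_week=full_since,
    )
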