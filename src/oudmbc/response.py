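"""Change-from-baseline treatment-response classification.

Treatment response is categorized by the percent decrease of the OUD
Symptom Checklist total from its week-0 baseline, combined with the
dichotomous past-2-week opioid-use flag:

* **full response** — more than 75% decrease AND no use in the past 2 weeks;
* **partial response** — 25-75% decrease (no use), OR more than 75%
  decrease with use;
* **minimal or nonresponse** — less than 25% decrease (including any
  worsening), OR 25-75% decrease with use.

The 25% and 75% boundaries belong to the middle band: a decrease of
exactly 25% or exactly 75% without use is a partial response. Percent
decrease is computed on exact rationals so these boundaries are never
blurred by floating-point rounding; with integer checklist totals every
boundary case is exactly representable. Full response is never assigned
while the patient reports ongoing opioid use.

Ongoing use with an in-band decrease deliberately downgrades the category:
use is dichotomized (any use vs none) rather than quantified, so a patient
with intermittent, reduced use lands in partial response at best.
"""

from __future__ import annotations

import enum
from fractions import Fraction

from pydantic import BaseModel, ConfigDict, Field

from .config import DEFAULT_CONFIG, EngineConfig


class DegenerateBaselineError(ValueError):
    """Raised when the baseline checklist total is 0.

    A patient entering treatment with a zero symptom score is not
    symptomatic; percent change from a zero baseline is undefined and the
    caller must handle the episode outside this classifier.
    """


class ResponseCategory(str, enum.Enum):
    minimal_nonresponse = "minimal_nonresponse"
    partial = "partial"
    full = "full"

    #: Clinical ordering, worst to best.
    @property
    def rank(self) -> int:
        return {"minimal_nonresponse": 0, "partial": 1, "full": 2}[self.value]


class ResponseAssessment(BaseModel):
    """A classified visit: scores, exact fractional decrease, category."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    baseline_total: int = Field(ge=1, le=11)
    current_total: int = Field(ge=0, le=11)
    percent_decrease: Fraction
    used_opioid_past_2wk: bool
    category: ResponseCategory


def percent_decrease(baseline_total: int, current_total: int) -> Fraction:
    """Exact fractional decrease from baseline; negative when worsening.

    ``Fraction(1)`` is a 100% decrease. Raises
    :class:`DegenerateBaselineError` when ``baseline_total`` is 0.
    """
    if baseline_total < 1:
        raise DegenerateBaselineError(
            f"baseline_total must be >= 1, got {baseline_total}"
        )
    return Fraction(baseline_total - current_total, baseline_total)


def classify_decrease(
    decrease: Fraction | float,
    used_opioid_past_2wk: bool,
    config: EngineConfig = DEFAULT_CONFIG,
) -> ResponseCategory:
    """Map a fractional decrease and the use flag to a response category.

    Band boundaries (default 1/4 and 3/4) are inclusive to the middle band.
    """
    lower, upper = config.lower_band, config.upper_band
    if decrease > upper:
        return (
            ResponseCategory.partial
            if used_opioid_past_2wk
            else ResponseCategory.full
        )
    if decrease >= lower:
        return (
            ResponseCategory.minimal_nonresponse
            if used_opioid_past_2wk
            else ResponseCategory.partial
        )
    return ResponseCategory.minimal_nonresponse


def classify_response(
    baseline_total: int,
    current_total: int,
    used_opioid_past_2wk: bool,
    config: EngineConfig = DEFAULT_CONFIG,
) -> ResponseCategory:
    """Classify a visit from integer checklist totals and the use flag."""
    return classify_decrease(
        percent_decrease(baseline_total, current_total),
        used_opioid_past_2wk,
        config,
    )


def assess_response(
    baseline_total: int,
    current_total: int,
    used_opioid_past_2wk: bool,
    config: EngineConfig = DEFAULT_CONFIG,
) -> ResponseAssessment:
    """Full assessment record for one visit."""
    dec = percent_decrease(baseline_total, current_total)
    return ResponseAssessment(
        baseline_total=baseline_total,
        current_total=current_total,
        percent_decrease=dec,
        used_opioid_past_2wk=used_opioid_past_2wk,
        category=classify_decrease(dec, used_opioid_past_2wk, config),
    )
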