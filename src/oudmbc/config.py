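"""Engine constants with YAML override support.

All tunable constants of the decision engine live in :class:`EngineConfig`.
Defaults encode the published rule set: a 24 mg/day buprenorphine ceiling,
biweekly acute-phase visits, 4-weekly continuation visits, the 25%/75%
change-from-baseline response bands, and the 1-missed-day adherence cutoff.
Overrides loaded from YAML are recorded on the instance so every derived
recommendation can state which constants were in force.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class EngineConfig(BaseModel):
    """Constants governing scoring bands, dosing limits and visit cadence."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    #: Maximum total daily buprenorphine dose (mg) the engine will ever recommend.
    dose_cap_mg: float = 24.0
    #: Dose step (mg) used for suggested-increase payloads and the simulator.
    dose_increment_mg: float = 4.0
    #: Initiation dose (mg): lower end of the therapeutic range.
    initiation_dose_mg: float = 8.0
    #: Weeks between visits during the acute (dose-finding) phase.
    acute_interval_weeks: int = 2
    #: Weeks between visits during the continuation phase.
    continuation_interval_weeks: int = 4
    #: Final scheduled acute-phase week; week-12 rules persist beyond it.
    max_acute_week: int = 12
    #: Lower band boundary: decreases below this are minimal/nonresponse.
    lower_band: Fraction = Fraction(1, 4)
    #: Upper band boundary: decreases above this (without use) are full response.
    upper_band: Fraction = Fraction(3, 4)
    #: Sustained full response (weeks) required to enter continuation.
    continuation_streak_weeks: float = 4.0
    #: Maximum missed days in the past week still counted as adherent.
    adherent_max_missed_days: int = 1
    #: Minimal/nonresponse trials beyond this week raise a trial-cap alert.
    minimal_trial_cap_weeks: float = 8.0
    #: Partial-response trials beyond this week raise a trial-cap alert.
    partial_trial_cap_weeks: float = 12.0
    #: Names of keys overridden from a config file (provenance).
    overridden: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "EngineConfig":
        if self.dose_cap_mg <= 0 or self.dose_increment_mg <= 0:
            raise ValueError("dose constants must be positive")
        if not (0 < self.lower_band < self.upper_band < 1):
            raise ValueError("band boundaries must satisfy 0 < lower < upper < 1")
        if not 0 <= self.adherent_max_missed_days <= 7:
            raise ValueError("adherent_max_missed_days must be within 0..7")
        return self


DEFAULT_CONFIG = EngineConfig()


def load_config(path: str | Path | None) -> EngineConfig:
    """Build an :class:`EngineConfig`, applying overrides from a YAML file.

    Band boundaries may be given as strings like ``"1/4"`` or as floats;
    fractions are preferred because they keep the 25%/75% boundaries exact.
    """
    if path is None:
        return DEFAULT_CONFIG
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(EngineConfig.model_fields) - {"overridden"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("lower_band", "upper_band"):
        if key in raw and isinstance(raw[key], str):
            raw[key] = Fraction(raw[key])
    raw["overridden"] = tuple(sorted(k for k in raw if k != "overridden"))
    return EngineConfig(**raw)
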