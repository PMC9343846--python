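"""Configuration models for the synthetic registry generator and pipeline.

Defaults reproduce the study conditions of the follow-up cohort: 34
recalled carriers and 291 never-recalled controls, group-wise E78*,
E78.0 and lipid-lowering-treatment prevalences taken from the printed
comparison table, an SLCO1B1 decreased-function allele frequency of
0.16, an 11:13:4 mix of adherence archetypes, registry follow-up
2004-01-01 .. 2022-03-31, and recall visits during 2016-2018.
"""

from __future__ import annotations

import datetime as dt
import enum

from pydantic import BaseModel, Field, model_validator


class Group(str, enum.Enum):
    RECALLED = "RECALLED"
    CONTROL = "CONTROL"


class Archetype(str, enum.Enum):
    """Adherence archetypes mirrored by the episode classifier."""

    POOR = "POOR"
    CONSISTENT_POST_VISIT = "CONSISTENT_POST_VISIT"
    PRIOR_CONSISTENT_TERMINATED = "PRIOR_CONSISTENT_TERMINATED"


class GroupRates(BaseModel):
    """A probability per study group."""

    recalled: float = Field(ge=0.0, le=1.0)
    control: float = Field(ge=0.0, le=1.0)

    def for_group(self, group: Group | str) -> float:
        return self.recalled if Group(group) is Group.RECALLED else self.control


class AdherenceParams(BaseModel):
    """Thresholds of the episode classifier, in days.

    Only the 6-month gap is quantified by the source rules; the
    remaining three are the package's defaults and all four are
    configurable.
    """

    gap_threshold_days: int = Field(default=183, ge=0)
    prior_consistent_days: int = Field(default=730, ge=1)
    shortly_after_days: int = Field(default=365, ge=0)
    ongoing_slack_days: int = Field(default=183, ge=0)
    combo_overlap_days: int = Field(default=30, ge=1)


class SimulationConfig(BaseModel):
    """Parameters of a synthetic cohort draw."""

    n_recalled: int = Field(default=34, ge=1)
    n_controls: int = Field(default=291, ge=1)
    p_e78: GroupRates = GroupRates(recalled=0.941, control=0.670)
    p_e780: GroupRates = GroupRates(recalled=0.824, control=0.460)
    p_llt: GroupRates = GroupRates(recalled=0.794, control=0.533)
    pgx_risk_allele_freq: float = Field(default=0.16, ge=0.0, le=1.0)
    archetype_mix: tuple[float, float, float] = (11.0, 13.0, 4.0)
    mean_codes_per_person: float = Field(default=41.0, gt=0.0)
    include_z_codes: bool = False
    nonresponse_rate: float = Field(default=0.25, ge=0.0, le=1.0)
    dual_carrier: bool = False
    followup_start: dt.date = dt.date(2004, 1, 1)
    followup_end: dt.date = dt.date(2022, 3, 31)
    visit_window: tuple[dt.date, dt.date] = (dt.date(2016, 1, 1), dt.date(2018, 12, 31))
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if any(w < 0 for w in self.archetype_mix):
            raise ValueError("archetype weights must be nonnegative")
        if sum(self.archetype_mix) <= 0:
            raise ValueError("archetype weights must sum > 0")
        v0, v1 = self.visit_window
        if not (self.followup_start < v0 < v1 < self.followup_end):
            raise ValueError(
                "dates must satisfy followup_start < visit_window[0] "
                "< visit_window[1] < followup_end"
            )
        for grp in ("recalled", "control"):
            if getattr(self.p_e780, grp) > getattr(self.p_e78, grp):
                raise ValueError(f"p_e780 must not exceed p_e78 for group {grp}")
        return self

    @property
    def visit_midpoint(self) -> dt.date:
        v0, v1 = self.visit_window
        return v0 + (v1 - v0) / 2
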