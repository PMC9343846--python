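"""SLCO1B1 statin-myopathy risk and statin-adjusted lipid values.

SLCO1B1 encodes the hepatic uptake transporter OATP1B1; its
decreased-function alleles (canonically tagged by c.521T>C, rs4149056)
raise circulating statin exposure and with it myopathy risk.  The
translation here is the three-category contract of the source
pipeline's output: 0 decreased-function alleles -> normal risk,
1 -> higher, 2 -> much higher.  The warning applies only to
simvastatin, atorvastatin and rosuvastatin.

On-statin lipid values are back-adjusted to an untreated estimate by
dividing total cholesterol by 0.8 and LDL-C by 0.7.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

#: Statins the SLCO1B1 myopathy warning applies to.
APPLICABLE_STATINS = frozenset({"simvastatin", "atorvastatin", "rosuvastatin"})

TC_STATIN_DIVISOR = 0.8
LDL_STATIN_DIVISOR = 0.7


class MyopathyRisk(str, enum.Enum):
    NORMAL = "NORMAL"
    HIGHER = "HIGHER"
    MUCH_HIGHER = "MUCH_HIGHER"


class InvalidGenotypeError(ValueError):
    pass


class InvalidMeasurementError(ValueError):
    pass


def slco1b1_risk(risk_allele_count: int) -> MyopathyRisk:
    """Map decreased-function allele count {0,1,2} to a risk category."""
    mapping = {0: MyopathyRisk.NORMAL, 1: MyopathyRisk.HIGHER, 2: MyopathyRisk.MUCH_HIGHER}
    try:
        return mapping[int(risk_allele_count)]
    except (KeyError, ValueError, TypeError):
        raise InvalidGenotypeError(
            f"risk allele count must be 0, 1 or 2; got {risk_allele_count!r}"
        ) from None


@dataclass(frozen=True)
class LipidMeasurement:
    """Lipid panel in mmol/L with optional statin back-adjustment."""

    total_cholesterol: float
    ldl_c: float
    on_statin: bool
    adjusted_tc: float = field(init=False)
    adjusted_ldl: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_cholesterol < 0 or self.ldl_c < 0:
            raise InvalidMeasurementError("lipid values must be nonnegative")
        tc = self.total_cholesterol / TC_STATIN_DIVISOR if self.on_statin else self.total_cholesterol
        ldl = self.ldl_c / LDL_STATIN_DIVISOR if self.on_statin else self.ldl_c
        object.__setattr__(self, "adjusted_tc", tc)
        object.__setattr__(self, "adjusted_ldl", ldl)


def adjust_lipids(total_cholesterol: float, ldl_c: float, on_statin: bool) -> LipidMeasurement:
    """Statin back-adjustment: TC/0.8 and LDL-C/0.7 when on a statin."""
    return LipidMeasurement(total_cholesterol, ldl_c, on_statin)


def risk_table(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-participant risk categories from an allele-count table."""
    out = genotypes[["participant_id"]].copy()
    out["myopathy_risk"] = [
        slco1b1_risk(c).value for c in genotypes["risk_allele_count"]
    ]
    return out


def build_pgx_profile(
    participant: dict,
    flags: dict | None,
    adherence: dict | None,
    risk: MyopathyRisk | str | None,
    lipids: LipidMeasurement | None,
    survey_summary: dict | None,
    prescribed_statins: set[str] | None = None,
) -> dict:
    """Join one LLT user's components into a flat profile record.

    Missing components are marked explicitly (None fields plus a
    ``missing`` list), never silently dropped.  All components must
    reference the participant of ``participant``.
    """
    pid = participant["participant_id"]
    for name, comp in (("flags", flags), ("adherence", adherence), ("survey", survey_summary)):
        if comp is not None and comp.get("participant_id", pid) != pid:
            raise ValueError(f"component {name} references a different participant")
    missing = [
        name
        for name, comp in (
            ("flags", flags),
            ("adherence", adherence),
            ("myopathy_risk", risk),
            ("lipids", lipids),
            ("survey", survey_summary),
        )
        if comp is None
    ]
    statins = prescribed_statins or set()
    profile = {
        "participant_id": pid,
        "age": participant.get("age"),
        "sex": participant.get("sex"),
        "fh_variant": participant.get("variant"),
        "has_e78_any": None if flags is None else flags.get("has_e78_any"),
        "has_e780": None if flags is None else flags.get("has_e780"),
        "adherence_class": None if adherence is None else adherence.get("adherence_class"),
        "myopathy_risk": None if risk is None else MyopathyRisk(risk).value,
        "adjusted_tc": None if lipids is None else lipids.adjusted_tc,
        "adjusted_ldl": None if lipids is None else lipids.adjusted_ldl,
        "statin_outside_warning_set": bool(statins - APPLICABLE_STATINS),
        "survey_treatment_adherence": None
        if survey_summary is None
        else survey_summary.get("treatment_adherence"),
        "missing": missing,
    }
    return profile
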