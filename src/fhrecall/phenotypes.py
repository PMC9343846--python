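"""ICD-10 phenotype flags and ATC-based treatment-user flags.

E78* ("disorders of lipoprotein metabolism") is the prefix family used
as the hypercholesterolemia proxy; E78.0 ("pure hypercholesterolemia")
is the code used clinically for FH.  Registry extracts come in both
dotted ("E78.0") and undotted ("E780") dialects, so codes are
normalized before comparison.  Diagnosis dates are deliberately ignored
for flags: the comparisons use ever-diagnosed semantics over the whole
EHR window.
"""

from __future__ import annotations

import re

import pandas as pd

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.?[0-9A-Z]{0,4})?$")


class Icd10FormatError(ValueError):
    """Raised for a code that does not parse as ICD-10."""


def normalize_icd10(code: str) -> str:
    """Uppercase and insert the dot of 4+ character undotted codes."""
    c = str(code).strip().upper()
    if "." not in c and len(c) > 3:
        c = c[:3] + "." + c[3:]
    if not _ICD10_RE.match(c):
        raise Icd10FormatError(f"malformed ICD-10 code: {code!r}")
    return c


def truncate_icd10(code: str) -> str:
    """Reduce a code to its 3-character stem (idempotent)."""
    return normalize_icd10(code)[:3]


def diagnosis_flags(
    diagnoses: pd.DataFrame,
    participants: pd.Series | list | None = None,
    strict_e780: bool = False,
) -> pd.DataFrame:
    """Per-participant E78 flags from a diagnosis table.

    Parameters
    ----------
    diagnoses:
        Columns ``participant_id`` and ``icd10``.
    participants:
        Optional full id list so participants without any record still
        get a (all-False) row.
    strict_e780:
        When True, E78.0 requires the exact 4-character code; the
        default also accepts E78.0x sub-subcodes.

    ``has_e780`` implies ``has_e78_any`` by construction.
    """
    codes = diagnoses["icd10"].map(normalize_icd10)
    is_e78 = codes.str.startswith("E78")
    is_e780 = codes == "E78.0" if strict_e780 else codes.str.startswith("E78.0")
    by_pid = pd.DataFrame(
        {
            "participant_id": diagnoses["participant_id"],
            "has_e78_any": is_e78,
            "has_e780": is_e780,
        }
    ).groupby("participant_id", sort=True).any()
    if participants is not None:
        by_pid = by_pid.reindex(pd.Index(participants, name="participant_id"), fill_value=False)
    return by_pid.reset_index()


def count_unique_diagnoses(
    diagnoses: pd.DataFrame,
    participants: pd.Series | list | None = None,
    exclude_z: bool = True,
) -> pd.Series:
    """Distinct 3-character codes per participant.

    Codes are truncated to their stems and each stem counted once per
    person; stems starting with "Z" (contact-with-health-services
    codes) are dropped when ``exclude_z``.  Invariant under record
    duplication and order.
    """
    stems = diagnoses["icd10"].map(truncate_icd10)
    keep = ~stems.str.startswith("Z") if exclude_z else pd.Series(True, index=stems.index)
    counts = (
        pd.DataFrame({"participant_id": diagnoses["participant_id"][keep], "stem": stems[keep]})
        .groupby("participant_id")["stem"]
        .nunique()
    )
    if participants is not None:
        counts = counts.reindex(pd.Index(participants, name="participant_id"), fill_value=0)
    return counts.rename("n_unique_codes3")


def identify_llt_users(
    prescriptions: pd.DataFrame,
    participants: pd.Series | list | None = None,
) -> pd.Series:
    """True for participants with >=1 purchase in ATC class C10*.

    C10 is the WHO ATC class of lipid-modifying agents (statins,
    ezetimibe, fibrates and combination products).
    """
    if "atc" not in prescriptions.columns:
        raise KeyError("prescription table lacks the required 'atc' column")
    atc = prescriptions["atc"].astype(str).str.upper()
    if len(prescriptions):
        is_llt = atc.str.startswith("C10")
        users = (
            pd.DataFrame({"participant_id": prescriptions["participant_id"], "llt": is_llt})
            .groupby("participant_id")["llt"]
            .any()
        )
    else:
        users = pd.Series(dtype=bool, name="llt")
    if participants is not None:
        users = users.reindex(pd.Index(participants, name="participant_id"), fill_value=False)
    return users.rename("is_llt_user")


def phenotype_table(
    participants: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    strict_e780: bool = False,
) -> pd.DataFrame:
    """Join flags and burden counts into one row per participant."""
    pids = participants["participant_id"]
    flags = diagnosis_flags(diagnoses, pids, strict_e780=strict_e780)
    flags["n_unique_codes3"] = count_unique_diagnoses(diagnoses, pids).to_numpy()
    flags["is_llt_user"] = identify_llt_users(prescriptions, pids).to_numpy()
    return participants.merge(flags, on="participant_id", validate="one_to_one")
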