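"""Carrier screening against the FH panel and cohort summaries.

FH variant carriers are found by matching variant calls (direct array
genotyping, imputation, or sequencing) against a user-supplied panel of
LDLR/APOB/PCSK9 variants.  Calls seen in both the genotyped and the
imputed set give the strongest array-based evidence tier (BOTH);
sequencing outranks both for the ``confirmed`` flag, mirroring Sanger
confirmation as the gold standard.  FH variants are treated as dominant
carrier flags; zygosity is not modelled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from fhrecall.config import Group

PANEL_GENES = frozenset({"APOB", "LDLR", "PCSK9"})
_SOURCES = frozenset({"genotyped", "imputed", "sequenced"})


class Evidence(str, enum.Enum):
    BOTH = "BOTH"
    GENOTYPED_ONLY = "GENOTYPED_ONLY"
    IMPUTED_ONLY = "IMPUTED_ONLY"
    SEQUENCED = "SEQUENCED"


class CallFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PanelVariant:
    gene: str
    protein_change: str
    rsid: str

    def __post_init__(self) -> None:
        if self.gene not in PANEL_GENES:
            raise ValueError(f"gene must be one of {sorted(PANEL_GENES)}, got {self.gene!r}")


@dataclass(frozen=True)
class CarrierRecord:
    participant_id: str
    variant: PanelVariant
    evidence: Evidence
    confirmed: bool


def load_panel(path: str | Path) -> list[PanelVariant]:
    """Read a panel CSV with columns gene, protein_change, rsid."""
    df = pd.read_csv(path)
    panel = [
        PanelVariant(r.gene, r.protein_change, str(r.rsid)) for r in df.itertuples(index=False)
    ]
    keys = [(v.gene, v.protein_change) for v in panel]
    if len(set(keys)) != len(keys):
        raise ValueError("panel has duplicate (gene, protein_change) entries")
    return panel


def screen_carriers(
    variant_calls: pd.DataFrame,
    panel: list[PanelVariant],
) -> list[CarrierRecord]:
    """One CarrierRecord per participant x panel variant found in calls.

    Matching is by rsid when present, else by (gene, protein_change).
    Calls outside the panel emit nothing; unknown source labels raise a
    format error naming the offending row.  Idempotent and
    order-independent over input rows.
    """
    by_rsid = {v.rsid: v for v in panel if v.rsid and v.rsid != "novel"}
    by_key = {(v.gene, v.protein_change): v for v in panel}
    sources: dict[tuple[str, PanelVariant], set[str]] = {}
    for i, row in enumerate(variant_calls.itertuples(index=False)):
        source = str(row.source).lower()
        if source not in _SOURCES:
            raise CallFormatError(f"row {i}: unknown source label {row.source!r}")
        variant = by_rsid.get(str(getattr(row, "rsid", "")))
        if variant is None:
            variant = by_key.get((str(row.gene), str(getattr(row, "protein_change", ""))))
        if variant is None:
            continue
        sources.setdefault((str(row.participant_id), variant), set()).add(source)
    records = []
    for (pid, variant), src in sorted(sources.items(), key=lambda kv: (kv[0][0], kv[0][1].rsid)):
        if "sequenced" in src:
            evidence, confirmed = Evidence.SEQUENCED, True
        elif {"genotyped", "imputed"} <= src:
            evidence, confirmed = Evidence.BOTH, True
        elif "genotyped" in src:
            evidence, confirmed = Evidence.GENOTYPED_ONLY, False
        else:
            evidence, confirmed = Evidence.IMPUTED_ONLY, False
        records.append(CarrierRecord(pid, variant, evidence, confirmed))
    return records


def assign_groups(
    carriers: list[CarrierRecord],
    recalled_ids: set[str] | list[str],
) -> pd.DataFrame:
    """Label every carrier RECALLED or CONTROL.

    Every recalled id must itself be a carrier; a dual-variant carrier
    appears once in the output.
    """
    recalled = set(recalled_ids)
    carrier_ids = {c.participant_id for c in carriers}
    stray = recalled - carrier_ids
    if stray:
        raise ValueError(f"recalled ids absent from carrier list: {sorted(stray)[:5]}")
    rows = [
        {
            "participant_id": pid,
            "group": (Group.RECALLED if pid in recalled else Group.CONTROL).value,
        }
        for pid in sorted(carrier_ids)
    ]
    return pd.DataFrame(rows, columns=["participant_id", "group"])


def summarize_cohort(
    participants: pd.DataFrame,
    carriers: list[CarrierRecord],
) -> dict[str, pd.DataFrame]:
    """Gene- and variant-level counts by group plus demographics.

    Percentages always carry their denominator: gene-level fractions of
    a cohort with dual-gene carriers are ambiguous unless the
    denominator (participants, not carrier records) is explicit.
    """
    group_of = participants.set_index("participant_id")["group"]
    rows = [
        {
            "participant_id": c.participant_id,
            "gene": c.variant.gene,
            "protein_change": c.variant.protein_change,
            "rsid": c.variant.rsid,
            "group": group_of.get(c.participant_id, "UNKNOWN"),
        }
        for c in carriers
    ]
    cdf = pd.DataFrame(rows)
    n_participants = participants["participant_id"].nunique()

    variant_counts = (
        cdf.groupby(["gene", "protein_change", "rsid", "group"], sort=True)
        .size()
        .unstack("group", fill_value=0)
        .reset_index()
    )
    for g in (Group.RECALLED.value, Group.CONTROL.value):
        if g not in variant_counts.columns:
            variant_counts[g] = 0
    variant_counts["total"] = (
        variant_counts[Group.RECALLED.value] + variant_counts[Group.CONTROL.value]
    )

    # a dual-variant carrier counts once per gene, once in the denominator
    gene_rows = []
    for gene, grp in cdf.drop_duplicates(["participant_id", "gene"]).groupby("gene"):
        n = grp["participant_id"].nunique()
        gene_rows.append(
            {
                "gene": gene,
                "n_recalled": int((grp["group"] == Group.RECALLED.value).sum()),
                "n_control": int((grp["group"] == Group.CONTROL.value).sum()),
                "n_total": n,
                "denominator": n_participants,
                "pct_of_participants": round(100.0 * n / n_participants, 1),
            }
        )
    gene_counts = pd.DataFrame(gene_rows)

    demo_rows = []
    for group, grp in participants.groupby("group"):
        row = {"group": group, "n": len(grp)}
        if "age" in grp.columns:
            row["median_age"] = float(grp["age"].median())
        if "bmi" in grp.columns:
            row["mean_bmi"] = round(float(grp["bmi"].mean()), 1)
        if "sex" in grp.columns:
            n_f = int((grp["sex"] == "F").sum())
            row["n_female"] = n_f
            row["pct_female"] = round(100.0 * n_f / len(grp), 1)
        if "smoking" in grp.columns:
            counts = grp["smoking"].fillna("Unknown").value_counts()
            for cat in ("Never", "Former", "Current", "Unknown"):
                row[f"smoking_{cat.lower()}"] = int(counts.get(cat, 0))
        demo_rows.append(row)
    demographics = pd.DataFrame(demo_rows)

    return {
        "gene_counts": gene_counts,
        "variant_counts": variant_counts,
        "demographics": demographics,
    }
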