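"""End-to-end orchestration: config -> report bundle.

Runs carrier screening, phenotype derivation, adherence
reconstruction, pharmacogenomic translation and the exact group
comparisons in order, writing every bundle table as CSV plus a run
manifest (resolved config, seed, package version) from which the
bundle is regenerable byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

import fhrecall
from fhrecall import synthetic
from fhrecall.adherence import classify_cohort, drug_exposure_summary, gantt_export
from fhrecall.config import AdherenceParams, Group, SimulationConfig
from fhrecall.pgx import risk_table
from fhrecall.phenotypes import phenotype_table
from fhrecall.stats import compare_groups
from fhrecall.survey import categorical_fractions, item_means, response_rate

log = logging.getLogger("fhrecall")


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, exc) from exc
            return out
        return inner
    return wrap


def load_tables(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the six linkage tables from a directory of CSVs."""
    in_dir = Path(in_dir)
    tables = {}
    for name in (
        "participants", "variant_calls", "diagnoses",
        "prescriptions", "pgx_genotypes", "survey_responses",
    ):
        path = in_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        df = pd.read_csv(path)
        for col in ("date", "purchase_date", "visit_date"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.date
        tables[name] = df
    return tables


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    in_dir: str | Path | None = None,
    params: AdherenceParams | None = None,
) -> dict:
    """Execute the full analysis and write the report bundle.

    With ``in_dir`` the six tables are read from CSV; otherwise a
    synthetic cohort is generated from ``config``.  Returns the bundle
    as a dict of DataFrames (plus the manifest).
    """
    params = params or AdherenceParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if in_dir is None:
        tables = _stage("simulate")(synthetic.generate_all)(config)
    else:
        tables = _stage("load")(load_tables)(in_dir)
    participants = tables["participants"]
    log.info("cohort: %d participants", len(participants))

    phenos = _stage("phenotypes")(phenotype_table)(
        participants, tables["diagnoses"], tables["prescriptions"]
    )
    log.info("phenotypes: %d rows", len(phenos))

    visit_dates = (
        participants.set_index("participant_id")["visit_date"].to_dict()
        if "visit_date" in participants.columns
        else config.visit_midpoint
    )
    adherence = _stage("adherence")(classify_cohort)(
        tables["prescriptions"], visit_dates, config.followup_end, params
    )
    gantt = _stage("adherence")(gantt_export)(
        tables["prescriptions"], adherence, params.gap_threshold_days
    )
    exposure = (
        _stage("adherence")(drug_exposure_summary)(tables["prescriptions"], params)
        if len(tables["prescriptions"])
        else pd.DataFrame(columns=["substance", "n_users", "total", "pct"])
    )
    log.info("adherence: %d users classified", len(adherence))

    risks = _stage("pharmacogenomics")(risk_table)(tables["pgx_genotypes"])
    phenos = phenos.merge(risks, on="participant_id", how="left")
    for cat in ("NORMAL", "HIGHER", "MUCH_HIGHER"):
        phenos[f"risk_{cat.lower()}"] = phenos["myopathy_risk"] == cat

    comparison = _stage("comparison")(compare_groups)(
        phenos,
        ["has_e78_any", "has_e780", "is_llt_user",
         "risk_normal", "risk_higher", "risk_much_higher"],
    )
    _check_internal_consistency(comparison)

    burden = phenos.groupby("group")["n_unique_codes3"].agg(["sum", "mean", "count"])
    burden["mean"] = burden["mean"].round(1)
    burden = burden.reset_index().rename(
        columns={"sum": "total_codes", "mean": "mean_codes", "count": "n_people"}
    )

    sv = tables["survey_responses"]
    recalled_ids = participants.loc[
        participants["group"] == Group.RECALLED.value, "participant_id"
    ]
    survey_summary = _stage("survey")(item_means)(sv) if len(sv) else pd.DataFrame(
        columns=["item_id", "item_mean", "n_respondents"]
    )
    survey_cats = _stage("survey")(categorical_fractions)(sv) if len(sv) else pd.DataFrame()
    n_returned = sv["participant_id"].nunique() if len(sv) else 0
    rate = response_rate(max(len(recalled_ids), 1), n_returned)

    manifest = {
        "package_version": fhrecall.__version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "adherence_params": params.model_dump(),
        "generated": in_dir is None,
        "n_participants": int(len(participants)),
        "survey_response_rate_pct": rate,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    bundle = {
        "phenotypes": phenos,
        "comparison": comparison,
        "diagnosis_burden": burden,
        "adherence_classes": adherence,
        "gantt": gantt,
        "drug_exposure": exposure,
        "survey_item_means": survey_summary,
        "survey_categorical": survey_cats,
    }
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _check_internal_consistency(comparison: pd.DataFrame) -> None:
    """Percentages in the bundle must re-derive from its own counts."""
    from fhrecall.stats import percentage

    for row in comparison.itertuples(index=False):
        for side in ("group1", "group2"):
            n = getattr(row, f"{side}_n")
            total = getattr(row, f"{side}_total")
            pct = getattr(row, f"{side}_pct")
            if percentage(n, total) != pct:
                raise AssertionError(
                    f"inconsistent percentage for {row.phenotype}/{side}: "
                    f"{pct} != {n}/{total}"
                )
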