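"""Synthetic registry generator for the full recall-by-genotype linkage.

Generates participant, variant-call, diagnosis, prescription,
pharmacogene-genotype and survey tables with the statistical structure
of the follow-up cohort, so every downstream stage is testable without
participant data.  All defaults are the study conditions: 34 recalled /
291 controls, group-wise E78*, E78.0 and LLT prevalences from the
printed comparison table, Hardy-Weinberg SLCO1B1 genotypes at allele
frequency 0.16, adherence archetypes mixed 11:13:4, follow-up
2004-01-01..2022-03-31 with visits in 2016-2018.

Determinism: every table is drawn from a stream keyed on
``(config.seed, table name)``, so identical configs give byte-identical
tables regardless of which generators are called or in what order.

Adherence archetypes are laid out so the episode classifier recovers
the intended class: POOR histories are sparse single-purchase episodes
separated by gaps well above six months; CONSISTENT_POST_VISIT
histories refill with sub-threshold gaps from around the visit until
the end of follow-up; PRIOR_CONSISTENT_TERMINATED histories sustain at
least two years of refills beginning well before the visit and then
stop, leaving the final six months of follow-up uncovered.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from fhrecall._vocab import (
    BACKGROUND_ICD10_STEMS,
    DEFAULT_VARIANT_TABLE,
    LLT_SUBSTANCES,
    PACKAGE_SIZES,
    SURVEY_CODEBOOK,
)
from fhrecall.config import Archetype, Group, SimulationConfig
from fhrecall.survey import Scale, likert_encode

_ARCHETYPES = (
    Archetype.POOR,
    Archetype.CONSISTENT_POST_VISIT,
    Archetype.PRIOR_CONSISTENT_TERMINATED,
)

#: Evidence-source mix for array-detected variants: carriers seen in both
#: the genotyped and imputed call sets dominate (225:33:33 in the cohort
#: the generator emulates).
_SOURCE_PROBS = {"both": 225 / 291, "genotyped": 33 / 291, "imputed": 33 / 291}

_DEFAULT_ITEM_DISTRIBUTIONS = {
    Scale.AGREEMENT: {
        "agree": 0.55, "slightly agree": 0.25, "unsure": 0.12,
        "slightly disagree": 0.05, "disagree": 0.03,
    },
    Scale.RATING: {
        "very good": 0.30, "good": 0.35, "unsure": 0.20,
        "satisfactory": 0.10, "unsatisfactory": 0.05,
    },
    Scale.CATEGORICAL: {"yes": 0.60, "yes, partly": 0.30, "no": 0.10},
}

_Z_STEMS = ["Z00", "Z03", "Z23", "Z25", "Z30"]


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    key = int.from_bytes(stream.encode(), "little") % (2**31)
    return np.random.default_rng([config.seed % (2**31), key])


def _uniform_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_cohort(
    config: SimulationConfig,
    variant_table: list[tuple] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant table and variant-call table for one synthetic cohort.

    Each participant carries exactly one panel variant drawn from the
    group-specific frequency column of ``variant_table`` (gene,
    protein_change, rsid, recalled weight, control weight); with
    ``config.dual_carrier`` the first recalled participant additionally
    carries a second variant in another gene.  Rsid "novel" variants
    are emitted as sequencing calls, others as genotyped/imputed calls
    with the BOTH-dominant source mix.
    """
    rng = _rng(config, "cohort")
    table = variant_table or DEFAULT_VARIANT_TABLE
    participants = []
    calls = []

    def sample_variant(group: Group):
        col = 3 if group is Group.RECALLED else 4
        weights = np.array([row[col] for row in table], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(table))
        return table[rng.choice(len(table), p=weights / weights.sum())]

    def emit_calls(pid: str, variant: tuple) -> None:
        gene, protein_change, rsid = variant[:3]
        if rsid == "novel":
            sources = ["sequenced"]
        else:
            kind = rng.choice(list(_SOURCE_PROBS), p=list(_SOURCE_PROBS.values()))
            sources = ["genotyped", "imputed"] if kind == "both" else [kind]
        for source in sources:
            calls.append(
                {"participant_id": pid, "gene": gene, "protein_change": protein_change,
                 "rsid": rsid, "source": source}
            )

    groups = [Group.RECALLED] * config.n_recalled + [Group.CONTROL] * config.n_controls
    for i, group in enumerate(groups):
        pid = f"P{i:05d}"
        variant = sample_variant(group)
        age = int(rng.integers(25, 85))
        visit_date = _uniform_date(rng, *config.visit_window)
        participants.append(
            {
                "participant_id": pid,
                "sex": "F" if rng.random() < 0.6 else "M",
                "birth_year": config.visit_window[0].year - age,
                "age": age,
                "bmi": round(float(np.clip(rng.normal(26.0, 4.5), 16.5, 52.0)), 1),
                "smoking": rng.choice(
                    ["Never", "Former", "Current", "Unknown"], p=[0.50, 0.23, 0.23, 0.04]
                ),
                "group": group.value,
                "variant_rsid": variant[2],
                "variant_gene": variant[0],
                "visit_date": visit_date,
            }
        )
        emit_calls(pid, variant)
        if config.dual_carrier and i == 0:
            second = next(row for row in table if row[0] != variant[0])
            emit_calls(pid, second)

    return pd.DataFrame(participants), pd.DataFrame(calls)


def generate_diagnoses(participants: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """ICD-10 diagnosis table with calibrated E78*/E78.0 prevalence.

    A single uniform draw per participant nests the outcomes — E78.0
    with probability p_e780, a non-.0 E78 subcode for the next
    p_e78 - p_e780 slice — so E78.0 carriers are a subset of E78*
    carriers at exactly the configured marginals.  Background burden is
    Poisson around the target mean of unique 3-character codes, drawn
    without replacement from an embedded non-E78, non-Z stem list.
    """
    rng = _rng(config, "diagnoses")
    records = []

    def add(pid: str, code: str) -> None:
        records.append(
            {
                "participant_id": pid,
                "icd10": code,
                "date": _uniform_date(rng, config.followup_start, config.followup_end),
            }
        )

    for row in participants.itertuples(index=False):
        p78 = config.p_e78.for_group(row.group)
        p780 = config.p_e780.for_group(row.group)
        u = rng.random()
        if u < p780:
            add(row.participant_id, "E78.0")
            if rng.random() < 0.3:
                add(row.participant_id, f"E78.{rng.integers(1, 6)}")
        elif u < p78:
            add(row.participant_id, f"E78.{rng.integers(1, 6)}")

        n_bg = int(min(len(BACKGROUND_ICD10_STEMS), rng.poisson(config.mean_codes_per_person - 1)))
        stems = rng.choice(len(BACKGROUND_ICD10_STEMS), size=n_bg, replace=False)
        for idx in stems:
            stem = BACKGROUND_ICD10_STEMS[idx]
            code = stem if rng.random() < 0.3 else f"{stem}.{rng.integers(0, 10)}"
            add(row.participant_id, code)
        if config.include_z_codes:
            for stem in rng.choice(_Z_STEMS, size=int(rng.integers(1, 4)), replace=False):
                add(row.participant_id, f"{stem}.{rng.integers(0, 10)}")

    return pd.DataFrame(records, columns=["participant_id", "icd10", "date"])


def _poor_history(rng, config, visit: dt.date):
    """Sparse single-purchase episodes with gaps far above the threshold."""
    purchases = []
    t = _uniform_date(rng, config.followup_start, visit)
    horizon = config.followup_end - dt.timedelta(days=400)
    while True:
        pills = int(rng.choice([28, 30]))
        purchases.append((t, 1, pills))
        t = t + dt.timedelta(days=pills + int(rng.integers(215, 600)))
        if t >= horizon:
            break
    return purchases

def _consistent_history(rng, config, visit: dt.date):
    """Refills with sub-threshold gaps from around the visit to follow-up end."""
    purchases = []
    t = visit + dt.timedelta(days=int(rng.integers(-300, 301)))
    t = max(t, config.followup_start)
    cover_end = t
    while t < config.followup_end:
        n_pack = int(rng.integers(1, 4))
        pills = int(rng.choice(PACKAGE_SIZES))
        purchases.append((t, n_pack, pills))
        cover_end = max(cover_end, t) + dt.timedelta(days=n_pack * pills)
        t = cover_end + dt.timedelta(days=int(rng.integers(-30, 121)))
    return purchases

def _terminated_history(rng, config, visit: dt.date):
    """>=2 years of refills starting well before the visit, then stop."""
    stop = visit + dt.timedelta(days=int(rng.integers(-150, 301)))
    start = stop - dt.timedelta(days=int(rng.integers(800, 2200)))
    start = max(start, config.followup_start)
    if (stop - start).days < 800:
        stop = start + dt.timedelta(days=800)
    purchases = []
    t, cover_end = start, start
    while t < stop:
        n_pack = int(rng.integers(1, 3))
        pills = int(rng.choice(PACKAGE_SIZES))
        purchases.append((t, n_pack, pills))
        cover_end = max(cover_end, t) + dt.timedelta(days=n_pack * pills)
        t = cover_end + dt.timedelta(days=int(rng.integers(-20, 101)))
    return purchases


_HISTORY_BUILDERS = {
    Archetype.POOR: _poor_history,
    Archetype.CONSISTENT_POST_VISIT: _consistent_history,
    Archetype.PRIOR_CONSISTENT_TERMINATED: _terminated_history,
}


def generate_prescriptions(
    participants: pd.DataFrame,
    config: SimulationConfig,
    with_archetypes: bool = False,
):
    """Prescription table for group-wise LLT users under archetype mixes.

    Users are drawn per group with ``p_llt`` and assigned an archetype
    by ``archetype_mix``; purchase histories are laid out so the
    episode classifier recovers the intended archetype at default
    thresholds.  Roughly a tenth of purchases are split into same-day
    duplicate rows to exercise the carry-forward adjustment.

    With ``with_archetypes`` also returns the per-user intended
    archetype assignments.
    """
    rng = _rng(config, "prescriptions")
    mix = np.asarray(config.archetype_mix, dtype=float)
    mix = mix / mix.sum()
    substances = list(LLT_SUBSTANCES)
    sub_probs = [0.45, 0.30, 0.10, 0.10, 0.05]

    rows, assignments = [], []
    for row in participants.itertuples(index=False):
        if rng.random() >= config.p_llt.for_group(row.group):
            continue
        archetype = _ARCHETYPES[rng.choice(3, p=mix)]
        visit = row.visit_date if isinstance(row.visit_date, dt.date) else pd.Timestamp(row.visit_date).date()
        purchases = _HISTORY_BUILDERS[archetype](rng, config, visit)
        substance = substances[rng.choice(len(substances), p=sub_probs)]
        for when, n_pack, pills in purchases:
            if rng.random() < 0.08:
                substance = substances[rng.choice(len(substances), p=sub_probs)]
            if when >= config.followup_end:
                continue
            splits = [(n_pack, pills)]
            if n_pack > 1 and rng.random() < 0.10:  # same-day duplicate purchase
                splits = [(1, pills), (n_pack - 1, pills)]
            for np_, pp in splits:
                rows.append(
                    {
                        "participant_id": row.participant_id,
                        "atc": LLT_SUBSTANCES[substance],
                        "substance": substance,
                        "purchase_date": when,
                        "n_packages": np_,
                        "pills_per_package": pp,
                    }
                )
        assignments.append(
            {"participant_id": row.participant_id, "archetype": archetype.value,
             "visit_date": visit}
        )

    cols = ["participant_id", "atc", "substance", "purchase_date", "n_packages", "pills_per_package"]
    prescriptions = pd.DataFrame(rows, columns=cols)
    if with_archetypes:
        return prescriptions, pd.DataFrame(
            assignments, columns=["participant_id", "archetype", "visit_date"]
        )
    return prescriptions


def generate_pgx_genotypes(participants: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """SLCO1B1 decreased-function allele counts under Hardy-Weinberg."""
    rng = _rng(config, "pgx")
    q = config.pgx_risk_allele_freq
    p = 1.0 - q
    counts = rng.choice(3, size=len(participants), p=[p * p, 2 * p * q, q * q])
    return pd.DataFrame(
        {"participant_id": participants["participant_id"], "risk_allele_count": counts}
    )


def generate_survey(
    recalled_participants: pd.DataFrame,
    config: SimulationConfig,
    item_distributions: dict | None = None,
) -> pd.DataFrame:
    """Survey responses for recalled participants with nonresponse.

    Nonresponse is sampled independently per recipient (default rate
    0.25).  ``item_distributions`` maps item_id to an answer->probability
    dict overriding the scale's default; probabilities must sum to 1.
    """
    rng = _rng(config, "survey")
    overrides = item_distributions or {}
    for item, dist in overrides.items():
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"response distribution for {item} sums to {total}, not 1")
    rows = []
    for row in recalled_participants.itertuples(index=False):
        if rng.random() < config.nonresponse_rate:
            continue
        for item in SURVEY_CODEBOOK:
            scale = Scale(item["scale"])
            dist = overrides.get(item["item_id"], _DEFAULT_ITEM_DISTRIBUTIONS[scale])
            answers = list(dist)
            answer = answers[rng.choice(len(answers), p=list(dist.values()))]
            numeric = (
                likert_encode(answer, scale) if scale is not Scale.CATEGORICAL else None
            )
            rows.append(
                {
                    "participant_id": row.participant_id,
                    "item_id": item["item_id"],
                    "scale": scale.value,
                    "raw_answer": answer,
                    "numeric": numeric,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "item_id", "scale", "raw_answer", "numeric"]
    )


def generate_all(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """All six linkage tables plus the intended-archetype key."""
    participants, calls = generate_cohort(config)
    prescriptions, archetypes = generate_prescriptions(participants, config, with_archetypes=True)
    recalled = participants[participants["group"] == Group.RECALLED.value]
    return {
        "participants": participants,
        "variant_calls": calls,
        "diagnoses": generate_diagnoses(participants, config),
        "prescriptions": prescriptions,
        "archetypes": archetypes,
        "pgx_genotypes": generate_pgx_genotypes(participants, config),
        "survey_responses": generate_survey(recalled, config),
    }


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> None:
    """Write the generated tables as CSV with ISO-8601 dates."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
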