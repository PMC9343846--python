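#!/usr/bin/env python
"""SLCO1B1 myopathy-risk translation and pharmacogenomic profiles.

Maps decreased-function allele counts to the three risk categories,
compares category prevalences between groups, and assembles flat
profiles for the recalled LLT users (variant, phenotype flags,
adherence class, risk, statin-adjusted lipids).
"""

import json
from pathlib import Path

import pandas as pd

from fhrecall.pgx import MyopathyRisk, adjust_lipids, build_pgx_profile, risk_table
from fhrecall.stats import compare_groups

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sd = ROOT / "synthetic"
    participants = pd.read_csv(sd / "participants.csv")
    genotypes = pd.read_csv(sd / "pgx_genotypes.csv")
    flags = pd.read_csv(ROOT / "phenotypes" / "phenotype_flags.csv")
    classes = pd.read_csv(ROOT / "adherence" / "adherence_classes.csv")

    risks = risk_table(genotypes)
    merged = participants.merge(risks, on="participant_id")
    for cat in MyopathyRisk:
        merged[f"risk_{cat.value.lower()}"] = merged["myopathy_risk"] == cat.value
    comparison = compare_groups(
        merged, ["risk_normal", "risk_higher", "risk_much_higher"]
    )
    print("myopathy risk categories by group:")
    print(comparison.to_string(index=False))

    # profiles for recalled LLT users (the follow-up's profile set)
    flagged = flags.set_index("participant_id")
    classed = classes.set_index("participant_id")
    risk_of = risks.set_index("participant_id")["myopathy_risk"]
    profiles = []
    recalled_users = flags[(flags["group"] == "RECALLED") & flags["is_llt_user"]]
    for row in recalled_users.itertuples(index=False):
        pid = row.participant_id
        p = participants.set_index("participant_id").loc[pid]
        profiles.append(
            build_pgx_profile(
                {"participant_id": pid, "age": int(p["age"]), "sex": p["sex"],
                 "variant": p["variant_rsid"]},
                flags={"participant_id": pid, "has_e78_any": bool(row.has_e78_any),
                       "has_e780": bool(row.has_e780)},
                adherence={"participant_id": pid,
                           "adherence_class": classed.loc[pid, "adherence_class"]}
                if pid in classed.index else None,
                risk=risk_of[pid],
                lipids=adjust_lipids(6.2, 4.1, on_statin=True),
                survey_summary=None,
            )
        )
    out = ROOT / "pgx"
    out.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(out / "risk_comparison.csv", index=False)
    pd.DataFrame(profiles).to_csv(out / "profiles.csv", index=False)
    (out / "profiles.json").write_text(json.dumps(profiles, indent=2, default=str))
    print(f"\nwrote {len(profiles)} pharmacogenomic profiles for recalled LLT users")


if __name__ == "__main__":
    main()
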