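#!/usr/bin/env python
"""Screen the synthetic variant calls against the FH panel and summarize.

Reproduces the variant-table structure of the cohort overview: carrier
records with evidence tiers, group assignment, per-gene and per-variant
counts with explicit denominators, and demographics.
"""

from pathlib import Path

import pandas as pd

from fhrecall._vocab import DEFAULT_VARIANT_TABLE
from fhrecall.cohort import PanelVariant, assign_groups, screen_carriers, summarize_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    participants = pd.read_csv(ROOT / "synthetic" / "participants.csv")
    calls = pd.read_csv(ROOT / "synthetic" / "variant_calls.csv")
    panel = [PanelVariant(g, p, r) for g, p, r, *_ in DEFAULT_VARIANT_TABLE]

    carriers = screen_carriers(calls, panel)
    recalled_ids = set(participants.loc[participants["group"] == "RECALLED", "participant_id"])
    groups = assign_groups(carriers, recalled_ids)
    print(f"{len(carriers)} carrier records; groups:\n{groups['group'].value_counts()}")

    summary = summarize_cohort(participants, carriers)
    out = ROOT / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    for name, df in summary.items():
        df.to_csv(out / f"{name}.csv", index=False)
        print(f"\n== {name} ==\n{df.to_string(index=False)}")


if __name__ == "__main__":
    main()
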