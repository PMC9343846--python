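#!/usr/bin/env python
"""EHR phenotype flags and exact two-tailed group comparisons.

Derives E78*/E78.0/LLT-user flags and diagnosis-burden counts from the
synthetic registry, then compares recalled vs control prevalences with
Fisher's exact test — the comparison-table analysis of the follow-up.
"""

from pathlib import Path

import pandas as pd

from fhrecall.phenotypes import phenotype_table
from fhrecall.stats import compare_groups

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sd = ROOT / "synthetic"
    participants = pd.read_csv(sd / "participants.csv")
    diagnoses = pd.read_csv(sd / "diagnoses.csv")
    prescriptions = pd.read_csv(sd / "prescriptions.csv")

    phenos = phenotype_table(participants, diagnoses, prescriptions)
    comparison = compare_groups(phenos, ["has_e78_any", "has_e780", "is_llt_user"])
    burden = phenos.groupby("group")["n_unique_codes3"].agg(["count", "sum", "mean"]).round(1)

    out = ROOT / "phenotypes"
    out.mkdir(parents=True, exist_ok=True)
    phenos.to_csv(out / "phenotype_flags.csv", index=False)
    comparison.to_csv(out / "group_comparison.csv", index=False)
    burden.to_csv(out / "diagnosis_burden.csv")

    print("group comparison (recalled vs control):")
    print(comparison.to_string(index=False))
    print("\ndiagnosis burden (unique 3-char codes, Z excluded):")
    print(burden.to_string())


if __name__ == "__main__":
    main()
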