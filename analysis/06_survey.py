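#!/usr/bin/env python
"""Score the feedback survey: item means, categorical fractions, rate.

Numeric (agreement and healthcare-rating) items are averaged on the
1-5 scale; categorical items are tabulated as answer fractions; the
response rate is reported against the recalled recipients.
"""

from pathlib import Path

import pandas as pd

from fhrecall.survey import categorical_fractions, item_means, response_rate

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sd = ROOT / "synthetic"
    participants = pd.read_csv(sd / "participants.csv")
    responses = pd.read_csv(sd / "survey_responses.csv")

    n_recalled = int((participants["group"] == "RECALLED").sum())
    n_returned = responses["participant_id"].nunique()
    rate = response_rate(n_recalled, n_returned)

    means = item_means(responses)
    cats = categorical_fractions(responses)

    out = ROOT / "survey"
    out.mkdir(parents=True, exist_ok=True)
    means.to_csv(out / "item_means.csv", index=False)
    cats.to_csv(out / "categorical_fractions.csv", index=False)

    print(f"survey returned by {n_returned} of {n_recalled} recipients ({rate}%)")
    print("\nhighest and lowest item means (1-5 scale):")
    ordered = means.sort_values("item_mean")
    print(pd.concat([ordered.head(3), ordered.tail(3)]).to_string(index=False))


if __name__ == "__main__":
    main()
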