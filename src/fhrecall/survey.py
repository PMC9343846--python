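"""Likert encoding and summaries for the recall feedback survey.

The 40-item instrument mixes three scale types: five-point agreement
items ("agree" .. "disagree"), five-point healthcare-rating items
("very good" .. "unsatisfactory"), and categorical items
(yes / yes, partly / no) that are tabulated as answer fractions and
never coerced to 1-5.  Numeric codes run 1-5 with values below 3
signifying negative attitudes.
"""

from __future__ import annotations

import enum

import pandas as pd


class Scale(str, enum.Enum):
    AGREEMENT = "AGREEMENT"
    RATING = "RATING"
    CATEGORICAL = "CATEGORICAL"


AGREEMENT_VOCAB = {
    "agree": 5,
    "slightly agree": 4,
    "unsure": 3,
    "slightly disagree": 2,
    "disagree": 1,
}

RATING_VOCAB = {
    "very good": 5,
    "good": 4,
    "unsure": 3,
    "satisfactory": 2,
    "unsatisfactory": 1,
}

CATEGORICAL_VOCAB = ("yes", "yes, partly", "no")


class VocabularyError(ValueError):
    """Raised for an answer outside the scale's vocabulary."""


def likert_encode(raw_answer: str, scale: Scale | str, item_id: str | None = None) -> int:
    """Map a raw answer string to its 1-5 numeric code."""
    scale = Scale(scale)
    vocab = {Scale.AGREEMENT: AGREEMENT_VOCAB, Scale.RATING: RATING_VOCAB}.get(scale)
    if vocab is None:
        raise VocabularyError(f"scale {scale.value} has no numeric encoding")
    key = str(raw_answer).strip().lower()
    if key not in vocab:
        where = f" (item {item_id})" if item_id else ""
        raise VocabularyError(f"unknown answer {raw_answer!r} for scale {scale.value}{where}")
    return vocab[key]


def likert_decode(numeric: int, scale: Scale | str) -> str:
    """Inverse of :func:`likert_encode` over a numeric scale."""
    scale = Scale(scale)
    vocab = {Scale.AGREEMENT: AGREEMENT_VOCAB, Scale.RATING: RATING_VOCAB}[scale]
    inverse = {v: k for k, v in vocab.items()}
    if numeric not in inverse:
        raise VocabularyError(f"numeric code {numeric} outside 1-5")
    return inverse[numeric]


def item_means(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-item mean of numeric codes plus respondent count.

    Only numeric-scale rows contribute; missing answers are excluded
    per item, and items with zero responses are reported with a null
    mean, never 0.
    """
    numeric = responses[responses["scale"].isin([Scale.AGREEMENT.value, Scale.RATING.value])]
    numeric = numeric.assign(numeric=pd.to_numeric(numeric["numeric"], errors="coerce"))
    numeric = numeric.dropna(subset=["numeric"])
    grouped = numeric.groupby("item_id")["numeric"].agg(["mean", "count"])
    grouped["mean"] = grouped["mean"].round(2)
    return grouped.rename(columns={"mean": "item_mean", "count": "n_respondents"}).reset_index()


def categorical_fractions(responses: pd.DataFrame) -> pd.DataFrame:
    """Answer fractions per categorical item."""
    cat = responses[responses["scale"] == Scale.CATEGORICAL.value]
    rows = []
    for item, grp in cat.groupby("item_id"):
        counts = grp["raw_answer"].value_counts()
        for answer, n in counts.items():
            rows.append(
                {"item_id": item, "answer": answer, "n": int(n),
                 "fraction": round(n / len(grp), 4)}
            )
    return pd.DataFrame(rows, columns=["item_id", "answer", "n", "fraction"])


def response_rate(n_sent: int, n_returned: int, ndigits: int = 0) -> float:
    """Survey response rate as a percentage."""
    if n_sent <= 0:
        raise ValueError("n_sent must be positive")
    if not 0 <= n_returned <= n_sent:
        raise ValueError("n_returned must be between 0 and n_sent")
    pct = 100.0 * n_returned / n_sent
    return round(pct, ndigits) if ndigits else round(pct)
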