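"""Prescription-refill adherence: supply intervals, episodes, classes.

Each pharmacy purchase covers ``n_packages x pills_per_package`` days at
the assumed one tablet per day.  When a purchase happens before the
previous supply runs out (same-day duplicates being the extreme case),
its coverage start is deferred to the running supply end — the standard
stockpiling carry-forward — so total covered days always equal total
dispensed days.  Intervals separated by an uncovered gap of more than
six months (183 days) split into distinct treatment episodes, and each
user's episode pattern relative to the feedback visit is classified
into one of three groups:

POOR
    neither of the patterns below;
CONSISTENT_POST_VISIT
    an episode covers the visit date (or starts within a year after it)
    and runs to within six months of the end of registry follow-up;
PRIOR_CONSISTENT_TERMINATED
    at least two years of continuous use beginning before the visit,
    but no supply at all in the final six months of follow-up.

CONSISTENT_POST_VISIT takes precedence: an ongoing user with an old
long episode is adherent now.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from fhrecall.config import AdherenceParams, Archetype

ALL_LLT = "ALL_LLT"


class InvalidRecordError(ValueError):
    pass


class NotAnLltUserError(ValueError):
    """Classification requires at least one purchase; caller must filter."""


@dataclass(frozen=True)
class PrescriptionRecord:
    """One pharmacy purchase — the atom of adherence reconstruction."""

    participant_id: str
    atc: str
    substance: str
    purchase_date: dt.date
    n_packages: int
    pills_per_package: int


@dataclass(frozen=True)
class SupplyInterval:
    """Half-open coverage interval [start, end) at day resolution."""

    participant_id: str
    substance: str
    start: dt.date
    end: dt.date

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclass(frozen=True)
class TreatmentEpisode:
    """Maximal run of supply with no uncovered gap above the threshold."""

    participant_id: str
    substance: str
    start: dt.date
    end: dt.date
    n_purchases: int

    @property
    def days(self) -> int:
        return (self.end - self.start).days


def days_supply(record: PrescriptionRecord) -> int:
    """Days covered by one purchase: packages x pills, one tablet/day."""
    if record.n_packages < 1 or record.pills_per_package < 1:
        raise InvalidRecordError(
            f"package and pill counts must be >= 1, got "
            f"{record.n_packages} x {record.pills_per_package} for "
            f"{record.participant_id} on {record.purchase_date}"
        )
    return record.n_packages * record.pills_per_package


def build_supply_intervals(
    records: list[PrescriptionRecord],
    substance: str = ALL_LLT,
) -> list[SupplyInterval]:
    """Carry-forward supply intervals for one participant.

    Records are sorted by purchase date; each purchase starts at
    max(purchase date, running supply end over all earlier purchases)
    and extends for its days of supply.  Supply conservation holds for
    any purchase pattern: the interval lengths sum to the total
    dispensed days.
    """
    if not records:
        return []
    pid = records[0].participant_id
    if any(r.participant_id != pid for r in records):
        raise InvalidRecordError("build_supply_intervals expects a single participant")
    out: list[SupplyInterval] = []
    supply_end: dt.date | None = None
    for rec in sorted(records, key=lambda r: r.purchase_date):
        start = rec.purchase_date
        if supply_end is not None and supply_end > start:
            start = supply_end
        end = start + dt.timedelta(days=days_supply(rec))
        out.append(SupplyInterval(pid, substance, start, end))
        supply_end = end
    return out


def merge_into_episodes(
    intervals: list[SupplyInterval],
    gap_threshold_days: int = 183,
) -> list[TreatmentEpisode]:
    """Merge intervals whose uncovered gap is <= the threshold.

    The split rule is strict: a gap of exactly ``gap_threshold_days``
    still merges; only strictly larger gaps start a new episode.
    """
    if gap_threshold_days < 0:
        raise ValueError("gap threshold must be nonnegative")
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda i: (i.start, i.end))
    episodes: list[TreatmentEpisode] = []
    cur_start, cur_end, n = ivs[0].start, ivs[0].end, 1
    for iv in ivs[1:]:
        gap = (iv.start - cur_end).days
        if gap > gap_threshold_days:
            episodes.append(
                TreatmentEpisode(iv.participant_id, iv.substance, cur_start, cur_end, n)
            )
            cur_start, cur_end, n = iv.start, iv.end, 1
        else:
            cur_end = max(cur_end, iv.end)
            n += 1
    episodes.append(TreatmentEpisode(ivs[0].participant_id, ivs[0].substance, cur_start, cur_end, n))
    return episodes


def classify_adherence(
    episodes: list[TreatmentEpisode],
    visit_date: dt.date,
    followup_end: dt.date,
    params: AdherenceParams | None = None,
) -> Archetype:
    """Assign one of the three adherence groups to an LLT user."""
    params = params or AdherenceParams()
    if not episodes:
        raise NotAnLltUserError("participant has no purchases; not an LLT user")
    if visit_date >= followup_end:
        raise ValueError("visit_date must precede followup_end")

    def covers_or_starts_soon(ep: TreatmentEpisode) -> bool:
        covers = ep.start <= visit_date < ep.end
        soon = 0 <= (ep.start - visit_date).days <= params.shortly_after_days
        return covers or soon

    for ep in episodes:
        if covers_or_starts_soon(ep) and (followup_end - ep.end).days <= params.ongoing_slack_days:
            return Archetype.CONSISTENT_POST_VISIT

    tail_start = followup_end - dt.timedelta(days=params.ongoing_slack_days)
    supply_in_tail = any(ep.end > tail_start for ep in episodes)
    long_prior = any(
        ep.days >= params.prior_consistent_days and ep.start < visit_date for ep in episodes
    )
    if long_prior and not supply_in_tail:
        return Archetype.PRIOR_CONSISTENT_TERMINATED
    return Archetype.POOR


def first_drug_continuation(records: list[PrescriptionRecord]) -> bool:
    """True when the last purchase is of a first-day substance."""
    if not records:
        raise InvalidRecordError("needs at least one purchase")
    recs = sorted(records, key=lambda r: r.purchase_date)
    first_day = recs[0].purchase_date
    first_substances = {r.substance for r in recs if r.purchase_date == first_day}
    return recs[-1].substance in first_substances


def records_from_frame(prescriptions: pd.DataFrame) -> dict[str, list[PrescriptionRecord]]:
    """Group a prescription table into per-participant record lists."""
    out: dict[str, list[PrescriptionRecord]] = {}
    for row in prescriptions.itertuples(index=False):
        date = row.purchase_date
        if not isinstance(date, dt.date) or isinstance(date, dt.datetime):
            date = pd.Timestamp(date).date()
        rec = PrescriptionRecord(
            participant_id=str(row.participant_id),
            atc=str(row.atc),
            substance=str(row.substance),
            purchase_date=date,
            n_packages=int(row.n_packages),
            pills_per_package=int(row.pills_per_package),
        )
        out.setdefault(rec.participant_id, []).append(rec)
    return out


def classify_cohort(
    prescriptions: pd.DataFrame,
    visit_dates: dict[str, dt.date] | dt.date,
    followup_end: dt.date,
    params: AdherenceParams | None = None,
) -> pd.DataFrame:
    """Classify every LLT user in a prescription table.

    ``visit_dates`` maps participant id to their feedback-visit date; a
    single date is used as a window-midpoint fallback for everyone.
    Episodes are pooled across substances (treatment-level adherence).
    """
    params = params or AdherenceParams()
    rows = []
    for pid, recs in records_from_frame(prescriptions).items():
        visit = visit_dates if isinstance(visit_dates, dt.date) else visit_dates[pid]
        episodes = merge_into_episodes(
            build_supply_intervals(recs), params.gap_threshold_days
        )
        rows.append(
            {
                "participant_id": pid,
                "adherence_class": classify_adherence(episodes, visit, followup_end, params).value,
                "n_episodes": len(episodes),
                "n_purchases": len(recs),
                "first_drug_continued": first_drug_continuation(recs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "adherence_class",
            "n_episodes",
            "n_purchases",
            "first_drug_continued",
        ],
    )


def _per_substance_episodes(
    recs: list[PrescriptionRecord], gap_threshold_days: int
) -> list[TreatmentEpisode]:
    episodes: list[TreatmentEpisode] = []
    by_substance: dict[str, list[PrescriptionRecord]] = {}
    for r in recs:
        by_substance.setdefault(r.substance, []).append(r)
    for substance, srecs in by_substance.items():
        ivs = [
            SupplyInterval(iv.participant_id, substance, iv.start, iv.end)
            for iv in build_supply_intervals(srecs)
        ]
        episodes.extend(merge_into_episodes(ivs, gap_threshold_days))
    return episodes


def drug_exposure_summary(
    prescriptions: pd.DataFrame,
    params: AdherenceParams | None = None,
) -> pd.DataFrame:
    """Ever-prescribed fraction per substance plus combination use.

    A combination user has concurrent rosuvastatin and (fenofibrate or
    ezetimibe) supply overlapping by at least ``combo_overlap_days``,
    or any purchase of a combination-product ATC code (C10B*).
    """
    params = params or AdherenceParams()
    per_user = records_from_frame(prescriptions)
    n_users = len(per_user)
    if n_users == 0:
        raise ValueError("user set is empty")
    substances = sorted({r.substance for recs in per_user.values() for r in recs})
    rows = []
    for s in substances:
        n = sum(any(r.substance == s for r in recs) for recs in per_user.values())
        rows.append({"substance": s, "n_users": n, "total": n_users,
                     "pct": round(100.0 * n / n_users, 1)})
    n_combo = sum(_is_combination_user(recs, params) for recs in per_user.values())
    rows.append({"substance": "combination", "n_users": n_combo, "total": n_users,
                 "pct": round(100.0 * n_combo / n_users, 1)})
    return pd.DataFrame(rows)


def _is_combination_user(recs: list[PrescriptionRecord], params: AdherenceParams) -> bool:
    if any(r.atc.upper().startswith("C10B") for r in recs):
        return True
    def coverage(substance: str) -> list[SupplyInterval]:
        sub = [r for r in recs if r.substance == substance]
        return build_supply_intervals(sub, substance) if sub else []
    rosu = coverage("rosuvastatin")
    for partner in ("fenofibrate", "ezetimibe"):
        for a in rosu:
            for b in coverage(partner):
                overlap = (min(a.end, b.end) - max(a.start, b.start)).days
                if overlap >= params.combo_overlap_days:
                    return True
    return False


def gantt_export(
    prescriptions: pd.DataFrame,
    adherence_classes: pd.DataFrame | None = None,
    gap_threshold_days: int = 183,
) -> pd.DataFrame:
    """Long-format per-substance episode table for timeline plotting.

    One row per (participant, substance) episode, participants ordered
    by adherence class (when given) then id, episodes by start date.
    """
    rows = []
    for pid, recs in records_from_frame(prescriptions).items():
        for ep in _per_substance_episodes(recs, gap_threshold_days):
            rows.append(
                {"participant_id": pid, "substance": ep.substance,
                 "start": ep.start, "end": ep.end, "n_purchases": ep.n_purchases}
            )
    table = pd.DataFrame(rows, columns=["participant_id", "substance", "start", "end", "n_purchases"])
    if adherence_classes is not None and len(table):
        order = {
            c: i
            for i, c in enumerate(
                ["POOR", "CONSISTENT_POST_VISIT", "PRIOR_CONSISTENT_TERMINATED"]
            )
        }
        cls = adherence_classes.set_index("participant_id")["adherence_class"]
        table["_rank"] = table["participant_id"].map(cls).map(order).fillna(len(order))
        table = table.sort_values(["_rank", "participant_id", "start"]).drop(columns="_rank")
    else:
        table = table.sort_values(["participant_id", "start"]) if len(table) else table
    return table.reset_index(drop=True)
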