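"""Acute respiratory infection (ARI) episodes from daily symptom diaries.

A diary day qualifies as an ARI day when it records at least one
A-symptom or at least two B-symptoms. A qualifying day while no episode
is open starts one; an episode ends on its last qualifying day once
``gap_days`` consecutive non-qualifying days have passed. Day 0 is the
date of birth and year n ends on day 365*n - 1 (leap days ignored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

A_SYMPTOMS = frozenset(
    {"fever", "wheezing", "wet_cough", "pneumonia_dx", "otitis_media_dx"}
)
B_SYMPTOMS = frozenset(
    {
        "dry_cough",
        "chills",
        "sore_throat",
        "runny_blocked_nose",
        "increased_sleep",
        "appetite_loss",
        "increased_attachment",
    }
)

MISSING_POLICIES = ("asymptomatic", "censor")


def year_end_day(year: int) -> int:
    """Last day index of year ``year`` (1-based): 365*year - 1."""
    return 365 * year - 1


@dataclass(frozen=True)
class DayRecord:
    """One diary day: recorded flag plus the A/B symptoms ticked."""

    day: int
    recorded: bool
    a_symptoms: frozenset = frozenset()
    b_symptoms: frozenset = frozenset()

    def __post_init__(self):
        if self.day < 0:
            raise ValidationError(f"day index must be >= 0, got {self.day}")
        if not self.a_symptoms <= A_SYMPTOMS:
            raise ValidationError(
                f"unknown A-symptoms: {sorted(self.a_symptoms - A_SYMPTOMS)}"
            )
        if not self.b_symptoms <= B_SYMPTOMS:
            raise ValidationError(
                f"unknown B-symptoms: {sorted(self.b_symptoms - B_SYMPTOMS)}"
            )
        if not self.recorded and (self.a_symptoms or self.b_symptoms):
            raise ValidationError(
                f"day {self.day}: symptoms present on an unrecorded day"
            )


@dataclass
class SymptomDiary:
    """Ordered per-day records for one subject."""

    subject_id: str
    days: list[DayRecord] = field(default_factory=list)

    def __post_init__(self):
        indices = [d.day for d in self.days]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValidationError(
                f"diary {self.subject_id}: day indices must be strictly increasing"
            )


@dataclass(frozen=True)
class Episode:
    """One ARI episode: inclusive day span plus its qualifying-day count."""

    start_day: int
    end_day: int
    n_symptom_days: int

    def __post_init__(self):
        if self.end_day < self.start_day:
            raise ValidationError("episode end_day before start_day")
        if self.n_symptom_days < 1:
            raise ValidationError("episode must contain at least one symptom day")


def is_ari_day(record: DayRecord) -> bool:
    """True iff the day has >= 1 A-symptom or >= 2 B-symptoms."""
    if not record.recorded:
        raise ValidationError(
            f"day {record.day} is unrecorded; missingness is the caller's policy"
        )
    return len(record.a_symptoms) >= 1 or len(record.b_symptoms) >= 2


def call_episodes(
    diary: SymptomDiary,
    gap_days: int = 3,
    missing_policy: str = "asymptomatic",
) -> list[Episode]:
    """Scan a diary and return its ARI episodes in chronological order.

    Under ``asymptomatic`` (default) unrecorded days count as
    non-qualifying; under ``censor`` they neither extend an episode nor
    advance the termination gap counter. The start rule is authoritative;
    the ``gap_days`` termination default of 3 is a configurable
    convention (the cohort's published episode algorithm owns the exact
    rule).
    """
    if gap_days < 1:
        raise ValidationError(f"gap_days must be >= 1, got {gap_days}")
    if missing_policy not in MISSING_POLICIES:
        raise ValidationError(f"missing_policy must be one of {MISSING_POLICIES}")
    if not diary.days:
        return []

    by_day = {d.day: d for d in diary.days}
    first, last = diary.days[0].day, diary.days[-1].day

    episodes: list[Episode] = []
    start = None
    last_qualifying = None
    n_symptom_days = 0
    gap = 0

    for day in range(first, last + 1):
        rec = by_day.get(day)
        missing = rec is None or not rec.recorded
        qualifying = False if missing else is_ari_day(rec)

        if qualifying:
            if start is None:
                start, n_symptom_days = day, 0
            last_qualifying = day
            n_symptom_days += 1
            gap = 0
        elif start is not None:
            if missing and missing_policy == "censor":
                continue  # gap counter pauses on censored days
            gap += 1
            if gap >= gap_days:
                episodes.append(Episode(start, last_qualifying, n_symptom_days))
                start, last_qualifying, n_symptom_days, gap = None, None, 0, 0

    if start is not None:
        episodes.append(Episode(start, last_qualifying, n_symptom_days))
    return episodes


def completeness(diary: SymptomDiary, window: tuple[int, int]) -> float:
    """Fraction of days in the inclusive ``(start, end)`` window recorded."""
    start, end = window
    if end < start:
        raise ValidationError(f"empty window ({start}, {end})")
    total = end - start + 1
    recorded = sum(1 for d in diary.days if start <= d.day <= end and d.recorded)
    return recorded / total


def cumulative_ari(episodes: list[Episode], year_ends: list[int]) -> np.ndarray:
    """Episodes started by each cutoff day; a non-decreasing count vector."""
    if any(b <= a for a, b in zip(year_ends, year_ends[1:])):
        raise ValidationError("year_ends must be strictly increasing")
    starts = np.array(sorted(e.start_day for e in episodes))
    return np.array([int((starts <= end).sum()) for end in year_ends])


# ---------------------------------------------------------------------------
# long-format diary TSV: subject_id, day, recorded, one column per symptom

_SYMPTOM_COLUMNS = sorted(A_SYMPTOMS) + sorted(B_SYMPTOMS)


def read_diary_table(path: str | Path) -> dict[str, SymptomDiary]:
    """Read a long-format diary TSV into one diary per subject."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("subject_id", "day", "recorded"):
        if col not in table.columns:
            raise ValidationError(f"diary table missing column {col!r}")
    symptom_cols = [c for c in _SYMPTOM_COLUMNS if c in table.columns]

    diaries: dict[str, list[DayRecord]] = {}
    for rec in table.to_dict("records"):
        recorded = rec["recorded"].strip().lower() in ("t", "true", "1", "yes")
        a = frozenset(
            c for c in symptom_cols
            if c in A_SYMPTOMS and rec[c].strip().lower() in ("t", "true", "1", "yes")
        )
        b = frozenset(
            c for c in symptom_cols
            if c in B_SYMPTOMS and rec[c].strip().lower() in ("t", "true", "1", "yes")
        )
        diaries.setdefault(rec["subject_id"], []).append(
            DayRecord(day=int(rec["day"]), recorded=recorded, a_symptoms=a, b_symptoms=b)
        )
    return {
        sid: SymptomDiary(sid, sorted(days, key=lambda d: d.day))
        for sid, days in diaries.items()
    }


def write_diary_table(diaries: dict[str, SymptomDiary], path: str | Path) -> None:
    rows = []
    for sid in sorted(diaries):
        for rec in diaries[sid].days:
            row = {"subject_id": sid, "day": rec.day, "recorded": "T" if rec.recorded else "F"}
            for col in _SYMPTOM_COLUMNS:
                row[col] = "T" if (col in rec.a_symptoms or col in rec.b_symptoms) else "F"
            rows.append(row)
    pd.DataFrame(rows, columns=["subject_id", "day", "recorded"] + _SYMPTOM_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_episode_table(episodes: dict[str, list[Episode]], path: str | Path) -> None:
    rows = [
        {
            "subject_id": sid,
            "start_day": e.start_day,
            "end_day": e.end_day,
            "n_symptom_days": e.n_symptom_days,
        }
        for sid in sorted(episodes)
        for e in episodes[sid]
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "start_day", "end_day", "n_symptom_days"]
    ).to_csv(path, sep="\t", index=False)
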