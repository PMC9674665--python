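"""Domain types, wearable CSV I/O, minute→hour→day aggregation, imputation.

Two wearable data shapes are supported:

* a Fitbit-style daily summary CSV (one row per participant-day with total
  steps and LPA/MPA/VPA/sedentary minutes), and
* a MOX2-5-style per-minute CSV (timestamp, IMA counts, a 60-second budget
  split over sedentary / weight-bearing / standing / LPA / MPA / VPA
  seconds, and steps per minute).

Every accepted minute must satisfy the 60-second budget exactly:
``sedentary + lpa + mpa + vpa + weight_bearing + standing == 60``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ecoach")

__all__ = [
    "MinuteRecord",
    "DailySummary",
    "ActivityDataset",
    "FormatError",
    "MINUTE_BUDGET_S",
    "DAILY_FIELDS",
    "DEFAULT_FITBIT_COLUMNS",
    "read_fitbit_daily",
    "write_fitbit_daily",
    "read_mox_minutes",
    "write_mox_minutes",
    "aggregate_to_hourly",
    "aggregate_to_daily",
    "impute_missing",
    "filter_min_days",
]

#: Seconds in one wearable minute; the per-minute time budget.
MINUTE_BUDGET_S = 60

#: Numeric daily-summary fields (the classifier feature candidates).
DAILY_FIELDS = ("steps", "lpa_min", "mpa_min", "vpa_min", "sedentary_min")

#: Column mapping for the public daily-activity CSV schema; configurable.
DEFAULT_FITBIT_COLUMNS: Mapping[str, str] = {
    "Id": "participant_id",
    "ActivityDate": "date",
    "TotalSteps": "steps",
    "LightlyActiveMinutes": "lpa_min",
    "FairlyActiveMinutes": "mpa_min",
    "VeryActiveMinutes": "vpa_min",
    "SedentaryMinutes": "sedentary_min",
}

MOX_COLUMNS = (
    "timestamp",
    "IMA",
    "sedentary_s",
    "weight_bearing_s",
    "standing_s",
    "lpa_s",
    "mpa_s",
    "vpa_s",
    "steps",
)


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclasses.dataclass(frozen=True)
class MinuteRecord:
    """One MOX2-5 sensor minute honouring the 60-second budget."""

    timestamp: dt.datetime
    ima: int
    sedentary_s: int = 0
    weight_bearing_s: int = 0
    standing_s: int = 0
    lpa_s: int = 0
    mpa_s: int = 0
    vpa_s: int = 0
    steps: int = 0

    def __post_init__(self) -> None:
        seconds = (
            self.sedentary_s
            + self.weight_bearing_s
            + self.standing_s
            + self.lpa_s
            + self.mpa_s
            + self.vpa_s
        )
        for name in ("ima", "sedentary_s", "weight_bearing_s", "standing_s",
                     "lpa_s", "mpa_s", "vpa_s", "steps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if seconds != MINUTE_BUDGET_S:
            raise ValueError(
                f"minute at {self.timestamp} violates the 60-second budget: "
                f"seconds sum to {seconds}"
            )


@dataclasses.dataclass(frozen=True)
class DailySummary:
    """Per-day activity summary: the classifier feature vector.

    Minutes are floats so that mean-imputed values and fractional
    moderate-equivalent constructions are representable; steps are integer.
    """

    participant_id: str
    date: dt.date
    steps: int
    lpa_min: float = 0.0
    mpa_min: float = 0.0
    vpa_min: float = 0.0
    sedentary_min: float = 0.0

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        for name in ("lpa_min", "mpa_min", "vpa_min", "sedentary_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.lpa_min + self.mpa_min + self.vpa_min + self.sedentary_min
        if total > 1440 + 1e-9:
            raise ValueError(
                f"daily minutes exceed 1440 for {self.participant_id} "
                f"on {self.date}: {total}"
            )


class ActivityDataset:
    """Ordered collection of daily summaries grouped by participant.

    Backed by a DataFrame with columns ``participant_id, date`` +
    :data:`DAILY_FIELDS`. Within each participant dates are strictly
    increasing with no duplicates. Field values may be NaN before
    imputation; :func:`impute_missing` removes them.
    """

    COLUMNS = ("participant_id", "date") + DAILY_FIELDS

    def __init__(self, df: pd.DataFrame, provenance: str = "fitbit_like"):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"dataset is missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["participant_id"] = df["participant_id"].astype(str)
        df = df.sort_values(["participant_id", "date"], kind="mergesort")
        df = df.reset_index(drop=True)
        dup = df.duplicated(subset=["participant_id", "date"])
        if dup.any():
            raise ValueError(
                "duplicate (participant, date) rows: "
                f"{df.loc[dup, ['participant_id', 'date']].to_dict('records')[:5]}"
            )
        self.df = df
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityDataset):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.df["participant_id"]))

    @classmethod
    def from_summaries(cls, summaries: Iterable[DailySummary],
                       provenance: str = "fitbit_like") -> "ActivityDataset":
        rows = [dataclasses.asdict(s) for s in summaries]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, provenance)

    def to_summaries(self) -> list[DailySummary]:
        """Materialise rows as DailySummary objects (requires no missing values)."""
        out = []
        for row in self.df.itertuples(index=False):
            out.append(DailySummary(
                participant_id=row.participant_id,
                date=row.date,
                steps=int(row.steps),
                lpa_min=float(row.lpa_min),
                mpa_min=float(row.mpa_min),
                vpa_min=float(row.vpa_min),
                sedentary_min=float(row.sedentary_min),
            ))
        return out

    def subset(self, participant_id: str) -> "ActivityDataset":
        df = self.df[self.df["participant_id"] == participant_id]
        if df.empty:
            raise KeyError(f"unknown participant {participant_id!r}")
        return ActivityDataset(df, self.provenance)


# ---------------------------------------------------------------------------
# Daily-summary CSV (Fitbit-style)
# ---------------------------------------------------------------------------

def read_fitbit_daily(
    paths: str | Path | Sequence[str | Path],
    column_map: Mapping[str, str] = DEFAULT_FITBIT_COLUMNS,
) -> ActivityDataset:
    """Read one or more daily-activity CSV files and merge them.

    Parsing is header-driven, so column order is irrelevant. Rows from
    multiple files are merged and de-duplicated on (participant, date),
    keeping the first occurrence; only the mapped fields are retained.

    Raises
    ------
    FormatError
        If a mandatory column is absent (the error names it) or a date
        cannot be parsed (the error carries the 1-based data row number).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        raw = pd.read_csv(path, dtype=str)
        missing = [src for src in column_map if src not in raw.columns]
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        sub = raw.loc[:, list(column_map)].rename(columns=dict(column_map))
        dates = pd.to_datetime(sub["date"], format="mixed", errors="coerce")
        if dates.isna().any():
            bad = int(np.flatnonzero(dates.isna().to_numpy())[0]) + 1
            raise FormatError(
                f"{path}: unparseable date {sub['date'].iloc[bad - 1]!r} "
                f"at data row {bad}"
            )
        sub["date"] = dates.dt.date
        for col in DAILY_FIELDS:
            sub[col] = pd.to_numeric(sub[col])
        frames.append(sub)
    merged = pd.concat(frames, ignore_index=True)
    dup = merged.duplicated(subset=["participant_id", "date"], keep="first")
    if dup.any():
        logger.info("dropping %d duplicate (participant, date) rows", int(dup.sum()))
    merged = merged[~dup]
    return ActivityDataset(merged, provenance="fitbit_like")


def write_fitbit_daily(
    dataset: ActivityDataset,
    path: str | Path,
    column_map: Mapping[str, str] = DEFAULT_FITBIT_COLUMNS,
) -> None:
    """Write a dataset back to the daily CSV dialect (inverse of the reader)."""
    inverse = {v: k for k, v in column_map.items()}
    out = dataset.df.rename(columns=inverse)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-minute CSV (MOX2-5-style)
# ---------------------------------------------------------------------------

def read_mox_minutes(path: str | Path) -> list[MinuteRecord]:
    """Read a per-minute sensor CSV; every row must satisfy the 60-s budget.

    Rows are returned sorted by timestamp; non-monotone input is sorted
    with a warning. A row violating the budget raises ValueError naming
    the offending 0-based row index.
    """
    raw = pd.read_csv(path)
    missing = [c for c in MOX_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records: list[MinuteRecord] = []
    timestamps = pd.to_datetime(raw["timestamp"])
    for idx, row in enumerate(raw.itertuples(index=False)):
        try:
            records.append(MinuteRecord(
                timestamp=timestamps.iloc[idx].to_pydatetime(),
                ima=int(row.IMA),
                sedentary_s=int(row.sedentary_s),
                weight_bearing_s=int(row.weight_bearing_s),
                standing_s=int(row.standing_s),
                lpa_s=int(row.lpa_s),
                mpa_s=int(row.mpa_s),
                vpa_s=int(row.vpa_s),
                steps=int(row.steps),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
    if any(b.timestamp < a.timestamp for a, b in zip(records, records[1:])):
        logger.warning("%s: non-monotone timestamps; sorting", path)
        records.sort(key=lambda r: r.timestamp)
    return records


def write_mox_minutes(records: Iterable[MinuteRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "timestamp": r.timestamp.isoformat(),
                "IMA": r.ima,
                "sedentary_s": r.sedentary_s,
                "weight_bearing_s": r.weight_bearing_s,
                "standing_s": r.standing_s,
                "lpa_s": r.lpa_s,
                "mpa_s": r.mpa_s,
                "vpa_s": r.vpa_s,
                "steps": r.steps,
            }
            for r in records
        ],
        columns=list(MOX_COLUMNS),
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregation: minute -> hour -> day
# ---------------------------------------------------------------------------

def _minutes_frame(minutes: Sequence[MinuteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": [m.timestamp for m in minutes],
            "sedentary_s": [m.sedentary_s for m in minutes],
            "lpa_s": [m.lpa_s for m in minutes],
            "mpa_s": [m.mpa_s for m in minutes],
            "vpa_s": [m.vpa_s for m in minutes],
            "steps": [m.steps for m in minutes],
        }
    )


def aggregate_to_hourly(minutes: Sequence[MinuteRecord]) -> pd.DataFrame:
    """Per-hour sums of seconds and steps — the inspectable intermediate.

    Returns a frame indexed by (date, hour) with summed seconds per
    intensity category, derived whole minutes (``*_min = seconds // 60``)
    and summed steps.
    """
    df = _minutes_frame(minutes)
    if df.empty:
        return pd.DataFrame()
    ts = pd.to_datetime(df.pop("timestamp"))
    grouped = df.groupby([ts.dt.date.rename("date"), ts.dt.hour.rename("hour")]).sum()
    for cat in ("sedentary", "lpa", "mpa", "vpa"):
        grouped[f"{cat}_min"] = grouped[f"{cat}_s"] // MINUTE_BUDGET_S
    return grouped


def aggregate_to_daily(
    minutes: Sequence[MinuteRecord], participant_id: str
) -> ActivityDataset:
    """Aggregate per-minute records to daily summaries.

    Seconds are summed over the whole day first and then integer-divided
    by 60, avoiding per-minute (or per-hour) truncation bias; steps are
    summed. Coverage gaps are allowed; an empty input yields an empty
    dataset.
    """
    df = _minutes_frame(minutes)
    if df.empty:
        empty = pd.DataFrame(columns=list(ActivityDataset.COLUMNS))
        return ActivityDataset(empty, provenance="mox_like")
    ts = pd.to_datetime(df.pop("timestamp"))
    daily = df.groupby(ts.dt.date.rename("date")).sum().reset_index()
    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "date": daily["date"],
            "steps": daily["steps"].astype(int),
            "lpa_min": (daily["lpa_s"] // MINUTE_BUDGET_S).astype(float),
            "mpa_min": (daily["mpa_s"] // MINUTE_BUDGET_S).astype(float),
            "vpa_min": (daily["vpa_s"] // MINUTE_BUDGET_S).astype(float),
            "sedentary_min": (daily["sedentary_s"] // MINUTE_BUDGET_S).astype(float),
        }
    )
    return ActivityDataset(out, provenance="mox_like")


# ---------------------------------------------------------------------------
# Imputation and retention filtering
# ---------------------------------------------------------------------------

def impute_missing(dataset: ActivityDataset) -> ActivityDataset:
    """Replace missing field values by the per-participant mean of that field.

    Steps are rounded to the nearest integer after imputation. A field
    with no observed values for some participant raises ValueError naming
    both.
    """
    df = dataset.df.copy()
    n_missing = int(df[list(DAILY_FIELDS)].isna().to_numpy().sum())
    for pid, idx in df.groupby("participant_id").groups.items():
        block = df.loc[idx, list(DAILY_FIELDS)]
        for field in DAILY_FIELDS:
            col = block[field]
            if col.isna().all():
                raise ValueError(
                    f"field {field!r} entirely missing for participant {pid!r}"
                )
            if col.isna().any():
                df.loc[idx, field] = col.fillna(col.mean())
    df["steps"] = df["steps"].round().astype(int)
    if n_missing:
        logger.info("imputed %d missing values with per-participant means", n_missing)
    return ActivityDataset(df, dataset.provenance)


def filter_min_days(dataset: ActivityDataset, min_days: int = 30) -> ActivityDataset:
    """Retain only participants with at least ``min_days`` distinct days.

    Implements the "more than a month of activity" retention criterion;
    the day count is configurable.
    """
    counts = dataset.df.groupby("participant_id")["date"].nunique()
    keep = counts[counts >= min_days].index
    dropped = sorted(set(dataset.participants) - set(keep))
    if dropped:
        logger.info("dropping %d participants below %d days: %s",
                    len(dropped), min_days, dropped[:5])
    df = dataset.df[dataset.df["participant_id"].isin(keep)]
    return ActivityDataset(df, dataset.provenance)
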