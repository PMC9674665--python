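"""Deterministic daily activity-level scoring.

Two rule tables drive the whole eCoaching pipeline:

* an IMA (intensity of movement/activity, counts per minute) banding that
  assigns each wearable minute to low / moderate / vigorous physical
  activity (LPA / MPA / VPA), and
* a five-class daily labeler that turns a day's step count and intensity
  minutes into an activity level ``sedentary (0) .. highly_active (4)``,
  following the WHO-style moderate-equivalent convention that one vigorous
  minute counts as two moderate minutes.

The daily rules are disjunctions of a step-count clause and a
weekly-moderate-equivalent clause; they overlap, and the labeler resolves
overlap by crediting the strongest matching level (highest score wins).
"""

from __future__ import annotations

import enum
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .core_data import DailySummary

__all__ = [
    "ActivityLevel",
    "IntensityBand",
    "classify_ima",
    "weekly_intensity_equivalent",
    "label_day",
    "daily_score",
]


class ActivityLevel(enum.IntEnum):
    """Five-class daily activity level; the integer value is the daily score."""

    SEDENTARY = 0
    LOW_ACTIVE = 1
    ACTIVE = 2
    MEDIUM_ACTIVE = 3
    HIGHLY_ACTIVE = 4

    @property
    def label(self) -> str:
        return self.name.lower()


class IntensityBand(enum.Enum):
    """Per-minute intensity band derived from the IMA count."""

    LPA = "LPA"
    MPA = "MPA"
    VPA = "VPA"


#: IMA band boundaries: LPA 0..400, MPA 401..800, VPA >= 801 counts/min.
LPA_IMA_MAX = 400
MPA_IMA_MAX = 800


def classify_ima(ima: int) -> IntensityBand:
    """Band a non-negative IMA count into LPA / MPA / VPA.

    The three bands partition the non-negative axis:
    ``0 <= ima <= 400`` is LPA, ``401 <= ima <= 800`` is MPA and
    ``ima >= 801`` is VPA.
    """
    if ima < 0:
        raise ValueError(f"IMA must be non-negative, got {ima}")
    if ima <= LPA_IMA_MAX:
        return IntensityBand.LPA
    if ima <= MPA_IMA_MAX:
        return IntensityBand.MPA
    return IntensityBand.VPA


def weekly_intensity_equivalent(day: "DailySummary") -> float:
    """Weekly moderate-equivalent minutes projected from one day.

    Computes ``(2 * VPA + MPA) * 7``: vigorous minutes count double
    (MPA = 2 VPA) and the daily total is extrapolated to a week so it can
    be compared against weekly guideline thresholds (90/210/300/360).
    """
    return (2.0 * day.vpa_min + day.mpa_min) * 7.0


def label_day(day: "DailySummary") -> ActivityLevel:
    """Assign the five-class daily activity level.

    Each level is a disjunction of an intensity clause (on the weekly
    moderate-equivalent W) and a step-count clause:

    ========================  ===================================  =====
    level                     rule                                 score
    ========================  ===================================  =====
    highly_active             (steps > 4999 and W >= 360)
                              or steps > 12499                     4
    medium_active             (steps > 4999 and 300 <= W < 360)
                              or 9999 < steps < 12500              3
    active                    (steps > 4999 and 210 <= W < 300)
                              or 7499 < steps < 10000              2
    low_active                (steps > 4999 and 90 <= W < 210)
                              or 4999 < steps < 7500               1
    sedentary                 steps < 5000 (LPA >= 0 is vacuous)   0
    ========================  ===================================  =====

    The clauses overlap; levels are evaluated from the highest score down
    and the first match is returned, so a day is always credited with the
    strongest activity evidence. The rules are total: any day with fewer
    than 5000 steps is sedentary, and the step clauses cover
    ``steps >= 5000`` without gaps.
    """
    steps = day.steps
    w = weekly_intensity_equivalent(day)

    if (steps > 4999 and w >= 360) or steps > 12499:
        return ActivityLevel.HIGHLY_ACTIVE
    if (steps > 4999 and 300 <= w < 360) or (9999 < steps < 12500):
        return ActivityLevel.MEDIUM_ACTIVE
    if (steps > 4999 and 210 <= w < 300) or (7499 < steps < 10000):
        return ActivityLevel.ACTIVE
    if (steps > 4999 and 90 <= w < 210) or (4999 < steps < 7500):
        return ActivityLevel.LOW_ACTIVE
    # sedentary: ((steps < 5000) and W < 90 and LPA >= 0) or (steps < 5000);
    # the second disjunct subsumes the first, implemented as printed.
    return ActivityLevel.SEDENTARY


def daily_score(level: ActivityLevel) -> int:
    """Daily goal score of a level (0-4); the currency summed into goal windows."""
    return int(level)
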