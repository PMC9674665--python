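"""Synthetic wearable-data generators with known ground-truth labels.

The generators emulate the two supported data shapes (daily summaries and
per-minute sensor streams) so that every downstream module — labeling,
feature screening, the learning harness, recommendations and the knowledge
graph — is testable without any external download.

Construction guarantees, not post-hoc checks:

* for every simulated day the deterministic daily labeler recovers the
  emitted ground-truth level exactly (features are sampled inside the
  level's step band with the weekly moderate-equivalent held below the
  next level's threshold);
* every simulated minute satisfies the 60-second budget, and its IMA count
  is drawn from the minute's intensity band (LPA 0-400, MPA 401-800,
  VPA >= 801);
* everything is reproducible from the seed.

Within-class draws are uniform over the rule-implied ranges; the rule
table gives boundaries, not distributions, so uniform is the least
committal choice and the ranges are configurable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    DAILY_FIELDS,
    ActivityDataset,
    MinuteRecord,
)
from .labeling import ActivityLevel

__all__ = [
    "SimulationConfig",
    "CLASS_STEP_RANGES",
    "simulate_daily",
    "simulate_minutes",
    "inject_missingness",
]

#: Inclusive step-count ranges per activity level, from the rule boundaries.
CLASS_STEP_RANGES: Mapping[int, tuple[int, int]] = {
    0: (0, 4999),
    1: (5000, 7499),
    2: (7500, 9999),
    3: (10000, 12499),
    4: (12500, 20000),
}

# Per-level cap on daily moderate-equivalent minutes (2*VPA + MPA), chosen
# strictly below the weekly threshold of the next level so the intensity
# clause never promotes a day out of its target step band:
# next-level weekly thresholds 90/210/300/360 -> daily caps 12/29/42/51.
_MODEQ_CAP = {0: 12, 1: 29, 2: 42, 3: 51, 4: 90}

#: Default class mix: skewed toward sedentary/low-active days, echoing the
#: left-heavy class distributions typical of cohort wearable data.
DEFAULT_CLASS_MIX = (0.30, 0.25, 0.20, 0.15, 0.10)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Cohort-simulation settings.

    ``class_mix`` is a probability vector over the five activity levels
    (sedentary .. highly active); ``missing_rate`` is the independent
    per-cell masking probability applied by :func:`inject_missingness`.
    """

    n_participants: int = 16
    n_days: int = 30
    class_mix: Sequence[float] = DEFAULT_CLASS_MIX
    missing_rate: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("n_participants and n_days must be positive")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (5,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must be 5 non-negative entries summing to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _draw_intensity(rng: np.random.Generator, level: int) -> tuple[int, int]:
    """Draw (vpa_min, mpa_min) with 2*vpa + mpa within the level's cap."""
    cap = _MODEQ_CAP[level]
    if level == 0:
        vpa = 0
    elif level == 4:
        vpa = int(rng.integers(0, 31))
    else:
        vpa = int(rng.integers(0, cap // 2 + 1))
    mpa = int(rng.integers(0, max(cap - 2 * vpa, 0) + 1))
    return vpa, mpa


def _sample_day(rng: np.random.Generator, level: int) -> dict:
    lo, hi = CLASS_STEP_RANGES[level]
    steps = int(rng.integers(lo, hi + 1))
    vpa, mpa = _draw_intensity(rng, level)
    lpa = int(rng.integers(20, 241))
    nonwear = int(rng.integers(0, 241))
    sedentary = 1440 - lpa - mpa - vpa - nonwear
    return {
        "steps": steps,
        "lpa_min": float(lpa),
        "mpa_min": float(mpa),
        "vpa_min": float(vpa),
        "sedentary_min": float(sedentary),
    }


def simulate_daily(config: SimulationConfig) -> tuple[ActivityDataset, np.ndarray]:
    """Simulate a labeled cohort of daily summaries.

    For each participant-day a target level is drawn from ``class_mix``;
    steps and intensity minutes are then sampled inside that level's rule
    ranges so the daily labeler reproduces the target exactly. Returns the
    dataset and the ground-truth labels aligned with its rows.
    """
    rng = np.random.default_rng(config.seed)
    start = dt.date(2024, 1, 1)
    rows, labels = [], []
    width = len(str(config.n_participants))
    for p in range(config.n_participants):
        pid = f"SP-{p + 1:0{width}d}"
        for d in range(config.n_days):
            level = int(rng.choice(5, p=np.asarray(config.class_mix, dtype=float)))
            day = _sample_day(rng, level)
            rows.append({"participant_id": pid,
                         "date": start + dt.timedelta(days=d), **day})
            labels.append(level)
    df = pd.DataFrame(rows, columns=list(ActivityDataset.COLUMNS))
    dataset = ActivityDataset(df, provenance="synthetic")
    # zero-padded ids and increasing dates keep generation order stable
    # through the dataset's canonical sort, so labels stay row-aligned
    assert dataset.df["participant_id"].tolist() == [r["participant_id"] for r in rows]
    return dataset, np.asarray(labels, dtype=int)


_IMA_RANGES = {"lpa": (1, 400), "mpa": (401, 800), "vpa": (801, 1500)}


def simulate_minutes(
    config: SimulationConfig, participant_id: str = "SP-1"
) -> list[MinuteRecord]:
    """Simulate a per-minute sensor stream for one participant.

    Each simulated day targets a level drawn from ``class_mix`` and is
    filled with 1440 one-category minutes (sedentary / standing / LPA /
    MPA / VPA seconds = 60) whose counts realise that level after daily
    aggregation; the day's step total is spread over its active minutes.
    A fully sedentary day has every minute sedentary with zero steps.
    IMA counts follow each minute's band.
    """
    rng = np.random.default_rng(config.seed)
    start = dt.datetime(2024, 1, 1)
    records: list[MinuteRecord] = []
    for d in range(config.n_days):
        level = int(rng.choice(5, p=np.asarray(config.class_mix, dtype=float)))
        day_start = start + dt.timedelta(days=d)
        if level == 0:
            kinds = ["sedentary"] * 1440
            steps_per_min = np.zeros(1440, dtype=int)
        else:
            lo, hi = CLASS_STEP_RANGES[level]
            steps_total = int(rng.integers(lo, hi + 1))
            vpa, mpa = _draw_intensity(rng, level)
            lpa = int(rng.integers(30, 121))
            standing = int(rng.integers(0, 61))
            sedentary = 1440 - lpa - mpa - vpa - standing
            kinds = (["lpa"] * lpa + ["mpa"] * mpa + ["vpa"] * vpa
                     + ["standing"] * standing + ["sedentary"] * sedentary)
            rng.shuffle(kinds)
            weights = np.array(
                [{"lpa": 1.0, "mpa": 2.0, "vpa": 3.0}.get(k, 0.0) for k in kinds]
            )
            steps_per_min = rng.multinomial(steps_total, weights / weights.sum())
        for i, kind in enumerate(kinds):
            ts = day_start + dt.timedelta(minutes=i)
            seconds = {f"{c}_s": 0 for c in
                       ("sedentary", "weight_bearing", "standing", "lpa", "mpa", "vpa")}
            seconds[f"{kind}_s"] = 60
            if kind in _IMA_RANGES:
                lo_i, hi_i = _IMA_RANGES[kind]
                ima = int(rng.integers(lo_i, hi_i + 1))
            elif kind == "standing":
                ima = int(rng.integers(0, 101))
            else:
                ima = 0
            records.append(MinuteRecord(
                timestamp=ts, ima=ima, steps=int(steps_per_min[i]), **seconds
            ))
    return records


def inject_missingness(
    dataset: ActivityDataset, rate: float, seed: int
) -> ActivityDataset:
    """Mask each numeric field value independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return ActivityDataset(dataset.df, dataset.provenance)
    rng = np.random.default_rng(seed)
    df = dataset.df.copy()
    values = df[list(DAILY_FIELDS)].astype(float)
    mask = rng.random(values.shape) < rate
    values = values.mask(mask)
    df[list(DAILY_FIELDS)] = values
    return ActivityDataset(df, dataset.provenance)
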