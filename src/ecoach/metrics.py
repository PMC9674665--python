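"""Confusion-matrix metrics, normality screening and feature selection.

Metrics are reported on the 0-100 scale used throughout the activity
classification tables (MCC on -100..+100). The multiclass scores are
one-vs-rest per class, combined by support-weighted averaging; MCC uses
the standard multiclass (R_k) generalisation.

Feature selection combines a Spearman-correlation pruning pass (remove
one feature from every pair with |r| >= 0.72, inclusive) with the final
feature set defined as the intersection of two candidate sets minus
context-irrelevant features.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DAILY_FIELDS, ActivityDataset

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "FeatureSet",
    "PruneResult",
    "compute_metrics",
    "normality_screen",
    "spearman_prune",
    "final_feature_set",
]

N_LEVELS = 5


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = actual level, columns = predicted level."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_labels(
        cls, actual: Sequence[int], predicted: Sequence[int], n_classes: int = N_LEVELS
    ) -> "ConfusionMatrix":
        actual = np.asarray(actual, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if actual.shape != predicted.shape:
            raise ValueError("actual and predicted must have equal length")
        counts = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(counts, (actual, predicted), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """Classification scores on the 0-100 scale (MCC on -100..+100)."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _multiclass_mcc(cm: np.ndarray) -> float:
    """Standard multiclass MCC (R_k statistic), in [-1, 1]."""
    c = float(np.trace(cm))
    s = float(cm.sum())
    p = cm.sum(axis=0).astype(float)  # predicted per class
    t = cm.sum(axis=1).astype(float)  # actual per class
    num = c * s - float(p @ t)
    den = math.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if den == 0.0:
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Derive the metric report from a confusion matrix.

    Per class k the one-vs-rest cells are TP = cm[k, k],
    FN = row k minus TP, FP = column k minus TP, TN = the rest; then

    * accuracy  = trace / total
    * precision = TP / (TP + FP)      (0 with a warning if no predictions)
    * recall    = TP / (TP + FN)
    * specificity = TN / (TN + FP)
    * F1 = 2PR / (P + R)

    averaged with class supports as weights and scaled to 0-100.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp

    support = counts.sum(axis=1)
    weights = support / total

    predicted_pos = tp + fp
    if (predicted_pos[support > 0] == 0).any():
        warnings.warn("class with zero predicted positives: precision set to 0",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted_pos > 0, tp / predicted_pos, 0.0)
        recall = np.where(support > 0, tp / np.where(support > 0, support, 1), 0.0)
        specificity = np.where(tn + fp > 0, tn / np.where(tn + fp > 0, tn + fp, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)

    return MetricReport(
        accuracy=float(tp.sum() / total) * 100.0,
        precision=float(weights @ precision) * 100.0,
        recall=float(weights @ recall) * 100.0,
        specificity=float(weights @ specificity) * 100.0,
        f1=float(weights @ f1) * 100.0,
        mcc=_multiclass_mcc(cm.counts) * 100.0,
    )


def normality_screen(values: Sequence[float], alpha: float = 0.05) -> dict[str, str]:
    """Screen a sample for gaussianity with three standard tests.

    Runs Shapiro-Wilk, D'Agostino K^2 and Anderson-Darling; each verdict is
    ``"gaussian"`` when the test fails to reject normality at ``alpha``
    (p > alpha, or statistic below the matching Anderson-Darling critical
    value), ``"non-gaussian"`` otherwise, or ``"degenerate"`` for a
    constant sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("normality screening needs at least 8 values")
    if np.ptp(x) == 0:
        return {t: "degenerate" for t in ("shapiro_wilk", "dagostino_k2",
                                          "anderson_darling")}
    verdicts: dict[str, str] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large-n p-value caveat from shapiro
        _, p_sw = stats.shapiro(x)
    verdicts["shapiro_wilk"] = "gaussian" if p_sw > alpha else "non-gaussian"
    _, p_da = stats.normaltest(x)
    verdicts["dagostino_k2"] = "gaussian" if p_da > alpha else "non-gaussian"
    with warnings.catch_warnings():
        # critical-value tables are exactly the alpha-level comparison wanted
        warnings.simplefilter("ignore", FutureWarning)
        ad = stats.anderson(x, dist="norm")
    # pick the critical value at the significance level closest to alpha
    levels = np.asarray(ad.significance_level, dtype=float) / 100.0
    crit = float(ad.critical_values[int(np.argmin(np.abs(levels - alpha)))])
    verdicts["anderson_darling"] = "gaussian" if ad.statistic < crit else "non-gaussian"
    return verdicts


@dataclasses.dataclass(frozen=True)
class FeatureSet:
    """A named set of candidate classifier features."""

    names: frozenset[str]

    def __init__(self, names: Iterable[str]):
        object.__setattr__(self, "names", frozenset(names))

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(sorted(self.names))

    def __len__(self) -> int:
        return len(self.names)


@dataclasses.dataclass(frozen=True)
class PruneResult:
    retained: FeatureSet
    dropped: tuple[str, ...]
    constant: tuple[str, ...]
    correlations: pd.DataFrame


# guard against floating-point round-off exactly at the inclusive threshold
_R_EPS = 1e-9


def spearman_prune(
    data: ActivityDataset | pd.DataFrame,
    r_threshold: float = 0.72,
    features: Sequence[str] | None = None,
) -> PruneResult:
    """Prune strongly rank-correlated features.

    Computes the pairwise Spearman matrix over ``features`` (default: the
    numeric daily fields) and greedily removes one feature from each pair
    with |r| >= ``r_threshold`` (inclusive) until none remain. From a
    correlated pair the feature with the larger mean absolute correlation
    to all others is dropped; ties break alphabetically. Constant features
    have undefined correlations; they are flagged and excluded from the
    pruning decisions.
    """
    df = data.df if isinstance(data, ActivityDataset) else data
    if features is None:
        features = [f for f in DAILY_FIELDS if f in df.columns]
    if len(features) < 2:
        raise ValueError("need at least 2 features to prune")
    if len(df) < 10:
        raise ValueError("need at least 10 rows to estimate correlations")
    block = df[list(features)].astype(float)
    constant = tuple(c for c in features if block[c].nunique() <= 1)
    active = [c for c in features if c not in constant]
    corr = block[active].corr(method="spearman")

    retained = list(active)
    dropped: list[str] = []
    while True:
        sub = corr.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        if sub.empty or sub.max().max() < r_threshold - _R_EPS:
            break
        i, j = np.unravel_index(int(np.argmax(sub.values)), sub.shape)
        a, b = sorted((sub.index[i], sub.columns[j]))
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        victim = b if mean_b > mean_a else a  # alphabetical tie-break via sort
        retained.remove(victim)
        dropped.append(victim)
    return PruneResult(
        retained=FeatureSet(retained),
        dropped=tuple(dropped),
        constant=constant,
        correlations=corr,
    )


def final_feature_set(
    fs1: FeatureSet | Iterable[str],
    fs2: FeatureSet | Iterable[str],
    exclude: Iterable[str] = ("calorie",),
) -> FeatureSet:
    """Final feature set: the intersection of two candidate sets.

    Context-irrelevant features (by default ``calorie``) are removed after
    intersecting. An empty result raises, advising manual review.
    """
    s1 = set(fs1.names if isinstance(fs1, FeatureSet) else fs1)
    s2 = set(fs2.names if isinstance(fs2, FeatureSet) else fs2)
    if not s1 or not s2:
        raise ValueError("both candidate feature sets must be non-empty")
    result = (s1 & s2) - set(exclude)
    if not result:
        raise ValueError(
            "final feature set is empty after intersection; review the "
            "candidate sets manually"
        )
    return FeatureSet(result)
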