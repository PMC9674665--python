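"""Model selection and the pretrain → transfer → incremental protocol.

Candidate classical classifiers (support-vector machines, naive Bayes,
decision trees, random forests, k-nearest neighbours, plus a most-frequent
dummy baseline) are ranked by stratified k-fold cross-validation with a
grid search inside every training split; the evaluation is repeated and
mean scores reported.

The coaching protocol then runs in three stages:

1. **Pretrain** — the best-ranked model is fitted on the large cohort
   dataset and stored as the global classifier ``G_C``.
2. **Transfer** — for each participant, the globally selected architecture
   and tuned hyperparameters are refitted on the global training pool
   combined with the participant's small personal dataset, producing a
   disjoint local classifier ``L_C``. (Classical estimators carry no
   reusable gradient state, so what transfers is the selected family, its
   tuned hyperparameters and the pooled training data.)
3. **Incremental** — each new day is classified with the current ``L_C``,
   the (features, predicted label) pair is appended to the personal pool
   and the model is refitted for the next day. Ground-truth labels can be
   used instead via ``use_true_label=True``.

A monthly rebuild refits ``G_C`` on the union of all active participants'
accumulated personal data.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core_data import ActivityDataset, DailySummary
from .labeling import ActivityLevel, label_day
from .metrics import ConfusionMatrix, MetricReport, compute_metrics

__all__ = [
    "FEATURES",
    "ModelSpec",
    "Leaderboard",
    "LeaderboardEntry",
    "FittedModel",
    "ModelStore",
    "default_model_specs",
    "make_xy",
    "train_and_rank",
    "pretrain_global",
    "transfer_fit",
    "fit_from_scratch",
    "incremental_step",
    "monthly_global_rebuild",
]

#: The final feature set used by every classifier.
FEATURES = ("sedentary_min", "lpa_min", "mpa_min", "vpa_min", "steps")

STORE_SCHEMA_VERSION = 1


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A classifier family and its hyperparameter grid."""

    family: str
    grid: Mapping[str, Sequence]

    def build(self, seed: int):
        return _build_estimator(self.family, seed)


def _build_estimator(family: str, seed: int):
    if family == "svc_linear":
        return SVC(kernel="linear", random_state=seed)
    if family == "svc_rbf":
        return SVC(kernel="rbf", random_state=seed)
    if family == "gaussian_nb":
        return GaussianNB()
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "knn":
        return KNeighborsClassifier()
    if family == "dummy_most_frequent":
        return DummyClassifier(strategy="most_frequent")
    raise ValueError(f"unknown model family {family!r}")


def default_model_specs() -> list[ModelSpec]:
    """The candidate model zoo with its tuning grids."""
    return [
        ModelSpec("svc_linear", {"C": [0.1, 1.0, 10.0]}),
        ModelSpec("svc_rbf", {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]}),
        ModelSpec("gaussian_nb", {}),
        ModelSpec("decision_tree", {"criterion": ["gini", "entropy"],
                                    "max_depth": [2, 4, 6, 8, 10, 12]}),
        ModelSpec("random_forest", {"n_estimators": [50, 100]}),
        ModelSpec("knn", {"n_neighbors": [2, 4]}),
        ModelSpec("dummy_most_frequent", {}),
    ]


@dataclasses.dataclass(frozen=True)
class LeaderboardEntry:
    spec: ModelSpec
    report: MetricReport          # mean over repetitions
    best_params: dict


@dataclasses.dataclass(frozen=True)
class Leaderboard:
    entries: tuple[LeaderboardEntry, ...]

    @property
    def best(self) -> LeaderboardEntry:
        """Best entry by mean accuracy; ties broken by MCC."""
        return max(self.entries, key=lambda e: (e.report.accuracy, e.report.mcc))


def make_xy(dataset: ActivityDataset,
            labels: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and labels for a dataset.

    When ``labels`` is omitted the deterministic daily labeler supplies
    them, making the target an exact function of the features.
    """
    X = dataset.df[list(FEATURES)].to_numpy(dtype=float)
    if labels is None:
        y = np.array([int(label_day(s)) for s in dataset.to_summaries()], dtype=int)
    else:
        y = np.asarray(labels, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("labels length does not match dataset")
    return X, y


def _grid_fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int,
              inner_cv: int = 3):
    """Grid-search a spec on a training split; returns (estimator, params)."""
    base = spec.build(seed)
    if not spec.grid:
        return base.fit(X, y), {}
    min_class = min(Counter(y).values())
    if min_class >= inner_cv:
        cv = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    else:
        cv = KFold(n_splits=min(inner_cv, max(2, len(y) // 2)), shuffle=True,
                   random_state=seed)
    search = GridSearchCV(base, dict(spec.grid), cv=cv, n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


def train_and_rank(
    dataset: ActivityDataset,
    specs: Sequence[ModelSpec] | None = None,
    k: int = 5,
    seed: int = 7,
    repetitions: int = 5,
    labels: Sequence[int] | None = None,
) -> Leaderboard:
    """Rank candidate models by repeated stratified k-fold evaluation.

    Each repetition shuffles the data, splits it into ``k`` stratified
    folds and, per fold, grid-searches the spec on the training split
    before scoring the held-out fold; fold confusion matrices are pooled
    into one per-repetition report and reports are averaged over
    repetitions. Fully deterministic given ``seed``.
    """
    if specs is None:
        specs = default_model_specs()
    X, y = make_xy(dataset, labels)
    if len(y) < k * 5:
        raise ValueError(f"need at least {k * 5} rows for {k}-fold ranking")
    present = np.unique(y)
    if len(present) < 5:
        import warnings
        warnings.warn(f"only levels {present.tolist()} present; metrics cover "
                      "present classes", RuntimeWarning, stacklevel=2)

    entries = []
    for spec in specs:
        reports = []
        param_votes: Counter = Counter()
        for rep in range(repetitions):
            rep_seed = seed + rep
            rng = np.random.default_rng(rep_seed)
            order = rng.permutation(len(y))
            Xs, ys = X[order], y[order]
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            cm = ConfusionMatrix(np.zeros((5, 5), dtype=int))
            for train_idx, test_idx in skf.split(Xs, ys):
                est, params = _grid_fit(spec, Xs[train_idx], ys[train_idx], seed)
                pred = est.predict(Xs[test_idx])
                cm = cm + ConfusionMatrix.from_labels(ys[test_idx], pred)
                param_votes[tuple(sorted(params.items()))] += 1
            reports.append(compute_metrics(cm))
        mean_report = MetricReport(**{
            f: float(np.mean([getattr(r, f) for r in reports]))
            for f in ("accuracy", "precision", "recall", "specificity", "f1", "mcc")
        })
        best_params = dict(param_votes.most_common(1)[0][0]) if param_votes else {}
        entries.append(LeaderboardEntry(spec, mean_report, best_params))
    return Leaderboard(tuple(entries))


# ---------------------------------------------------------------------------
# Model store and the transfer / incremental protocol
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FittedModel:
    """A fitted classifier artifact with its training metadata."""

    estimator: object
    family: str
    params: dict
    feature_names: tuple[str, ...]
    version: int
    n_rows: int

    def predict_one(self, day: DailySummary) -> ActivityLevel:
        x = np.array([[getattr(day, f) for f in self.feature_names]], dtype=float)
        return ActivityLevel(int(self.estimator.predict(x)[0]))


@dataclasses.dataclass
class _LocalState:
    model: FittedModel
    pool_X: np.ndarray
    pool_y: np.ndarray
    active: bool = True


class ModelStore:
    """Holds the global classifier, per-participant local classifiers and
    their training pools; persists to a directory of joblib artifacts plus
    a JSON manifest carrying the schema version and feature signature."""

    def __init__(self, global_model: FittedModel,
                 global_X: np.ndarray, global_y: np.ndarray, seed: int = 7):
        self.global_model = global_model
        self._global_X = np.asarray(global_X, dtype=float)
        self._global_y = np.asarray(global_y, dtype=int)
        self.locals: dict[str, _LocalState] = {}
        self.seed = seed
        self.version = global_model.version

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schema_version": STORE_SCHEMA_VERSION,
            "feature_names": list(self.global_model.feature_names),
            "version": self.version,
            "seed": self.seed,
            "participants": sorted(self.locals),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(
            {"global_model": self.global_model, "global_X": self._global_X,
             "global_y": self._global_y, "locals": self.locals},
            directory / "store.joblib",
        )

    @classmethod
    def load(cls, directory: str | Path,
             expected_features: Sequence[str] = FEATURES) -> "ModelStore":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest["schema_version"] != STORE_SCHEMA_VERSION:
            raise ValueError(
                f"store schema version {manifest['schema_version']} is not "
                f"supported (expected {STORE_SCHEMA_VERSION})"
            )
        if tuple(manifest["feature_names"]) != tuple(expected_features):
            raise ValueError(
                "feature-set signature mismatch: store was trained on "
                f"{manifest['feature_names']}, expected {list(expected_features)}"
            )
        payload = joblib.load(directory / "store.joblib")
        store = cls(payload["global_model"], payload["global_X"],
                    payload["global_y"], seed=manifest["seed"])
        store.locals = payload["locals"]
        store.version = manifest["version"]
        return store

    # -- helpers ------------------------------------------------------------

    def local_model(self, participant_id: str) -> FittedModel:
        try:
            return self.locals[participant_id].model
        except KeyError:
            raise KeyError(f"no local model for participant {participant_id!r}")

    def set_active(self, participant_id: str, active: bool) -> None:
        self.locals[participant_id].active = active


def pretrain_global(
    source: ActivityDataset,
    specs: Sequence[ModelSpec] | None = None,
    k: int = 5,
    seed: int = 7,
    repetitions: int = 5,
    labels: Sequence[int] | None = None,
) -> ModelStore:
    """Stage 1: rank candidates on the cohort data and store the best
    model, fitted on all of it, as the global classifier (version 1)."""
    if len(source) == 0:
        raise ValueError("cannot pretrain on an empty dataset")
    board = train_and_rank(source, specs, k=k, seed=seed,
                           repetitions=repetitions, labels=labels)
    best = board.best
    X, y = make_xy(source, labels)
    est = best.spec.build(seed)
    est.set_params(**best.best_params)
    est.fit(X, y)
    model = FittedModel(est, best.spec.family, best.best_params,
                        tuple(FEATURES), version=1, n_rows=len(y))
    return ModelStore(model, X, y, seed=seed)


def transfer_fit(
    store: ModelStore,
    personal: ActivityDataset,
    participant_id: str,
    labels: Sequence[int] | None = None,
    include_global_data: bool = True,
) -> ModelStore:
    """Stage 2: create the participant's local classifier.

    The globally selected architecture and tuned hyperparameters are
    refitted on the pretraining pool combined with the personal rows
    (``include_global_data=False`` restricts the refit to personal rows
    only). Local models are disjoint across participants: fitting one
    never touches another.
    """
    if len(personal) == 0:
        raise ValueError("transfer requires non-empty personal data")
    Xp, yp = make_xy(personal, labels)
    if include_global_data:
        X = np.vstack([store._global_X, Xp])
        y = np.concatenate([store._global_y, yp])
    else:
        X, y = Xp, yp
    est = clone(store.global_model.estimator)
    est.fit(X, y)
    model = FittedModel(est, store.global_model.family,
                        dict(store.global_model.params),
                        store.global_model.feature_names,
                        version=1, n_rows=len(y))
    store.locals[participant_id] = _LocalState(model, Xp, yp)
    return store


def fit_from_scratch(
    personal: ActivityDataset,
    spec: ModelSpec | None = None,
    seed: int = 7,
    labels: Sequence[int] | None = None,
) -> FittedModel:
    """Baseline for the transfer comparison: grid-search and fit the same
    family on the personal rows alone (no pretrained knowledge)."""
    if spec is None:
        spec = default_model_specs()[3]  # decision tree
    X, y = make_xy(personal, labels)
    est, params = _grid_fit(spec, X, y, seed, inner_cv=2)
    return FittedModel(est, spec.family, params, tuple(FEATURES),
                       version=1, n_rows=len(y))


def incremental_step(
    store: ModelStore,
    participant_id: str,
    day: DailySummary,
    use_true_label: bool = False,
) -> tuple[ActivityLevel, int]:
    """Stage 3: classify day n, then retrain the local model for day n+1.

    The day is predicted with the current local classifier; the (features,
    predicted label) pair — or the rule-derived true label with
    ``use_true_label=True`` — joins the personal pool and the model is
    refitted. Returns the prediction and the new local version.
    """
    state = store.locals.get(participant_id)
    if state is None:
        raise KeyError(f"no local model for participant {participant_id!r}")
    model = state.model
    if model.feature_names != tuple(FEATURES):
        raise ValueError("feature-set signature mismatch for local model")
    prediction = model.predict_one(day)
    label = int(label_day(day)) if use_true_label else int(prediction)
    x = np.array([[getattr(day, f) for f in model.feature_names]], dtype=float)
    state.pool_X = np.vstack([state.pool_X, x])
    state.pool_y = np.append(state.pool_y, label)
    X = np.vstack([store._global_X, state.pool_X])
    y = np.concatenate([store._global_y, state.pool_y])
    est = clone(model.estimator)
    est.fit(X, y)
    state.model = FittedModel(est, model.family, dict(model.params),
                              model.feature_names,
                              version=model.version + 1, n_rows=len(y))
    return prediction, state.model.version


def monthly_global_rebuild(store: ModelStore) -> ModelStore:
    """Refit the global classifier on all active participants' pooled data.

    Participants whose coaching cycle has ended (``active=False``) are
    excluded. Local models are untouched; the global version increments.
    """
    blocks = [(s.pool_X, s.pool_y) for s in store.locals.values() if s.active]
    if not blocks or sum(len(y) for _, y in blocks) == 0:
        raise ValueError("no active participant has contributed data")
    X = np.vstack([b[0] for b in blocks])
    y = np.concatenate([b[1] for b in blocks])
    est = clone(store.global_model.estimator)
    est.fit(X, y)
    store.version += 1
    store.global_model = FittedModel(
        est, store.global_model.family, dict(store.global_model.params),
        store.global_model.feature_names, version=store.version, n_rows=len(y),
    )
    return store
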