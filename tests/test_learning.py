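import numpy as np
import pytest

from ecoach import (
    ModelSpec,
    ModelStore,
    SimulationConfig,
    default_model_specs,
    fit_from_scratch,
    incremental_step,
    monthly_global_rebuild,
    pretrain_global,
    simulate_daily,
    train_and_rank,
    transfer_fit,
)
from ecoach.learning import FEATURES, make_xy

DT_SPEC = [s for s in default_model_specs() if s.family == "decision_tree"]
DUMMY_SPEC = [s for s in default_model_specs()
              if s.family == "dummy_most_frequent"]


@pytest.fixture(scope="module")
def cohort():
    return simulate_daily(SimulationConfig(n_participants=10, n_days=40, seed=7))


@pytest.fixture(scope="module")
def store(cohort):
    ds, labels = cohort
    return pretrain_global(ds, DT_SPEC, labels=labels, repetitions=2)


def _personal(seed, n_days=23):
    return simulate_daily(SimulationConfig(n_participants=1, n_days=n_days,
                                           seed=seed))


def test_default_specs_cover_the_model_zoo():
    families = {s.family for s in default_model_specs()}
    assert families == {"svc_linear", "svc_rbf", "gaussian_nb", "decision_tree",
                        "random_forest", "knn", "dummy_most_frequent"}
    dt = DT_SPEC[0]
    assert list(dt.grid["criterion"]) == ["gini", "entropy"]
    assert list(dt.grid["max_depth"]) == [2, 4, 6, 8, 10, 12]


class TestTrainAndRank:
    def test_decision_tree_separates_rule_labeled_data(self, cohort):
        ds, labels = cohort
        board = train_and_rank(ds, DT_SPEC, labels=labels, repetitions=2)
        assert board.best.report.accuracy >= 99.0

    def test_dummy_baseline_near_majority_rate(self):
        ds, labels = simulate_daily(SimulationConfig(
            n_participants=10, n_days=50, class_mix=(0.2,) * 5, seed=3))
        board = train_and_rank(ds, DUMMY_SPEC, labels=labels, repetitions=2)
        majority = np.bincount(labels).max() / len(labels) * 100
        assert board.entries[0].report.accuracy == pytest.approx(majority, abs=1.0)

    def test_same_seed_gives_identical_leaderboard(self, cohort):
        ds, labels = cohort
        a = train_and_rank(ds, DT_SPEC, labels=labels, repetitions=2)
        b = train_and_rank(ds, DT_SPEC, labels=labels, repetitions=2)
        assert a == b

    def test_too_few_rows_rejected(self):
        ds, labels = simulate_daily(SimulationConfig(n_participants=1,
                                                     n_days=10, seed=1))
        with pytest.raises(ValueError, match="at least"):
            train_and_rank(ds, DT_SPEC, labels=labels)


class TestGlobalPretrain:
    def test_fit_reaches_by_construction_separability(self, store, cohort):
        ds, labels = cohort
        X, y = make_xy(ds, labels)
        assert (store.global_model.estimator.predict(X) == y).mean() >= 0.99

    def test_empty_source_rejected(self):
        import pandas as pd

        from ecoach import ActivityDataset

        empty = ActivityDataset(pd.DataFrame(columns=list(
            ActivityDataset.COLUMNS)))
        with pytest.raises(ValueError):
            pretrain_global(empty, DT_SPEC)

    def test_persist_load_round_trip(self, store, cohort, tmp_path):
        ds, labels = cohort
        X, _ = make_xy(ds, labels)
        store.save(tmp_path / "store")
        loaded = ModelStore.load(tmp_path / "store")
        probe = X[:50]
        assert (loaded.global_model.estimator.predict(probe)
                == store.global_model.estimator.predict(probe)).all()

    def test_feature_signature_mismatch_rejected_on_load(self, store, tmp_path):
        store.save(tmp_path / "store")
        with pytest.raises(ValueError, match="signature"):
            ModelStore.load(tmp_path / "store",
                            expected_features=("steps", "lpa_min"))


class TestTransfer:
    def test_local_model_classifies_held_out_days(self, store):
        correct = 0
        for seed in range(20):
            personal, labels = _personal(100 + seed)
            transfer_fit(store, personal, "T-1", labels=labels)
            probe, probe_labels = simulate_daily(SimulationConfig(
                n_participants=1, n_days=1, seed=500 + seed))
            pred = store.local_model("T-1").predict_one(probe.to_summaries()[0])
            correct += int(pred) == probe_labels[0]
        assert correct >= 19  # >= 0.95 over 20 seeds

    def test_zero_personal_rows_rejected(self, store):
        import pandas as pd

        from ecoach import ActivityDataset

        empty = ActivityDataset(pd.DataFrame(columns=list(
            ActivityDataset.COLUMNS)))
        with pytest.raises(ValueError):
            transfer_fit(store, empty, "T-0")

    def test_local_models_are_disjoint(self, store):
        import joblib

        pa, la = _personal(31)
        pb, lb = _personal(32)
        transfer_fit(store, pa, "A", labels=la)
        transfer_fit(store, pb, "B", labels=lb)
        hash_b = joblib.hash(store.local_model("B").estimator)
        # refitting A must not alter B's artifact
        transfer_fit(store, pa, "A", labels=la)
        assert joblib.hash(store.local_model("B").estimator) == hash_b

    def test_unknown_participant_rejected_in_later_calls(self, store):
        with pytest.raises(KeyError):
            store.local_model("NOBODY")

    def test_transfer_beats_scratch_on_small_personal_data(self, store):
        wins = losses = 0
        for seed in range(15):
            personal, pl = _personal(700 + seed, n_days=10)
            test, tl = simulate_daily(SimulationConfig(
                n_participants=1, n_days=30, seed=900 + seed))
            X, y = make_xy(test, tl)
            transfer_fit(store, personal, "CMP", labels=pl)
            acc_t = (store.local_model("CMP").estimator.predict(X) == y).mean()
            scratch = fit_from_scratch(personal, labels=pl)
            acc_s = (scratch.estimator.predict(X) == y).mean()
            wins += acc_t > acc_s
            losses += acc_t < acc_s
        assert wins > losses  # directional benefit of the pretrained stage


class TestIncremental:
    def test_seven_days_bump_version_by_seven(self, store):
        personal, labels = _personal(55)
        transfer_fit(store, personal, "INC", labels=labels)
        week, _ = simulate_daily(SimulationConfig(n_participants=1, n_days=7,
                                                  seed=56))
        versions = []
        for day in week.to_summaries():
            _, version = incremental_step(store, "INC", day)
            versions.append(version)
        assert versions == [2, 3, 4, 5, 6, 7, 8]

    def test_daily_predictions_accurate_on_separable_data(self, store):
        correct = total = 0
        for seed in range(10):
            personal, labels = _personal(800 + seed)
            transfer_fit(store, personal, "ACC", labels=labels)
            week, week_labels = simulate_daily(SimulationConfig(
                n_participants=1, n_days=7, seed=850 + seed))
            for day, truth in zip(week.to_summaries(), week_labels):
                pred, _ = incremental_step(store, "ACC", day)
                correct += int(pred) == truth
                total += 1
        assert correct / total >= 0.95

    def test_missing_local_model_rejected(self, store):
        personal, _ = _personal(60)
        with pytest.raises(KeyError):
            incremental_step(store, "GHOST", personal.to_summaries()[0])


class TestMonthlyRebuild:
    def test_training_rows_equal_union_of_pools(self, cohort):
        ds, labels = cohort
        store = pretrain_global(ds, DT_SPEC, labels=labels, repetitions=2)
        pa, la = _personal(71, n_days=20)
        pb, lb = _personal(72, n_days=25)
        transfer_fit(store, pa, "A", labels=la)
        transfer_fit(store, pb, "B", labels=lb)
        store = monthly_global_rebuild(store)
        assert store.global_model.n_rows == 45
        assert store.version == 2

    def test_ended_participant_excluded(self, cohort):
        ds, labels = cohort
        store = pretrain_global(ds, DT_SPEC, labels=labels, repetitions=2)
        pa, la = _personal(81, n_days=20)
        pb, lb = _personal(82, n_days=25)
        transfer_fit(store, pa, "A", labels=la)
        transfer_fit(store, pb, "B", labels=lb)
        store.set_active("B", False)
        store = monthly_global_rebuild(store)
        assert store.global_model.n_rows == 20

    def test_rebuild_does_not_degrade_accuracy(self, cohort):
        # one-sided check over repeated seeds: the rebuilt global model,
        # trained on a cohort-scale union of personal pools, is not
        # systematically worse than its predecessor on fresh data
        from scipy.stats import binomtest

        ds, labels = cohort
        losses = wins = 0
        for seed in range(10):
            store = pretrain_global(ds, DT_SPEC, labels=labels, repetitions=1,
                                    seed=7)
            for i in range(8):
                p, pl = simulate_daily(SimulationConfig(
                    n_participants=1, n_days=40, seed=1000 + 10 * seed + i))
                transfer_fit(store, p, f"P{i}", labels=pl)
            before = store.global_model
            store = monthly_global_rebuild(store)
            fresh, fl = simulate_daily(SimulationConfig(
                n_participants=2, n_days=40, seed=2000 + seed))
            X, y = make_xy(fresh, fl)
            acc_before = (before.estimator.predict(X) == y).mean()
            acc_after = (store.global_model.estimator.predict(X) == y).mean()
            wins += acc_after > acc_before
            losses += acc_after < acc_before
        n = wins + losses
        if n:
            p_worse = binomtest(losses, n, alternative="greater").pvalue
            assert p_worse > 0.05

    def test_no_contributors_rejected(self, store, cohort):
        ds, labels = cohort
        fresh = pretrain_global(ds, DT_SPEC, labels=labels, repetitions=1)
        with pytest.raises(ValueError):
            monthly_global_rebuild(fresh)


def test_feature_set_matches_final_selection():
    assert set(FEATURES) == {"sedentary_min", "lpa_min", "mpa_min",
                             "vpa_min", "steps"}
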