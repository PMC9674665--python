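import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ecoach import (
    ActivityDataset,
    DailySummary,
    MinuteRecord,
    aggregate_to_daily,
    aggregate_to_hourly,
    filter_min_days,
    impute_missing,
    read_fitbit_daily,
    read_mox_minutes,
    write_fitbit_daily,
    write_mox_minutes,
)
from ecoach.core_data import DAILY_FIELDS, FormatError

FITBIT_HEADER = ("Id,ActivityDate,TotalSteps,LightlyActiveMinutes,"
                 "FairlyActiveMinutes,VeryActiveMinutes,SedentaryMinutes\n")


def _write_fitbit(path, rows):
    path.write_text(FITBIT_HEADER + "".join(rows))
    return path


class TestFitbitReader:
    def test_passthrough_of_handwritten_rows(self, tmp_path):
        p = _write_fitbit(tmp_path / "a.csv", [
            "1503960366,4/12/2016,4000,200,10,5,800\n",
            "1503960366,4/13/2016,8000,250,20,10,700\n",
            "1503960366,4/14/2016,13000,300,30,15,600\n",
        ])
        ds = read_fitbit_daily(p)
        assert len(ds) == 3
        assert ds.df["steps"].tolist() == [4000, 8000, 13000]
        assert ds.df["date"].iloc[0] == dt.date(2016, 4, 12)

    def test_column_permutation_yields_identical_dataset(self, tmp_path):
        p1 = _write_fitbit(tmp_path / "a.csv", ["7,2016-04-12,4000,200,10,5,800\n"])
        p2 = tmp_path / "b.csv"
        p2.write_text(
            "SedentaryMinutes,TotalSteps,Id,ActivityDate,VeryActiveMinutes,"
            "FairlyActiveMinutes,LightlyActiveMinutes\n"
            "800,4000,7,2016-04-12,5,10,200\n"
        )
        assert read_fitbit_daily(p1) == read_fitbit_daily(p2)

    def test_merge_deduplicates_shared_row(self, tmp_path):
        row = "7,2016-04-12,4000,200,10,5,800\n"
        p1 = _write_fitbit(tmp_path / "a.csv", [row])
        p2 = _write_fitbit(tmp_path / "b.csv",
                           [row, "7,2016-04-13,6000,200,10,5,800\n"])
        ds = read_fitbit_daily([p1, p2])
        assert len(ds) == 2

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("Id,ActivityDate,TotalSteps\n7,2016-04-12,4000\n")
        with pytest.raises(FormatError, match="FairlyActiveMinutes"):
            read_fitbit_daily(p)

    def test_unparseable_date_reports_row_number(self, tmp_path):
        p = _write_fitbit(tmp_path / "a.csv", [
            "7,2016-04-12,4000,200,10,5,800\n",
            "7,not-a-date,5000,200,10,5,800\n",
        ])
        with pytest.raises(FormatError, match="row 2"):
            read_fitbit_daily(p)

    def test_write_read_round_trip(self, tmp_path, labeled_cohort):
        ds, _ = labeled_cohort
        out = tmp_path / "rt.csv"
        write_fitbit_daily(ds, out)
        again = read_fitbit_daily(out)
        pd.testing.assert_frame_equal(
            ds.df, again.df, check_dtype=False, check_exact=False)


class TestMoxReader:
    def test_budget_compliant_row_accepted(self):
        m = MinuteRecord(dt.datetime(2024, 1, 1), ima=300,
                         sedentary_s=30, lpa_s=20, mpa_s=5, vpa_s=5)
        assert m.sedentary_s + m.lpa_s + m.mpa_s + m.vpa_s == 60

    def test_budget_violation_reports_row_index(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "timestamp,IMA,sedentary_s,weight_bearing_s,standing_s,"
            "lpa_s,mpa_s,vpa_s,steps\n"
            "2024-01-01T00:00:00,0,60,0,0,0,0,0,0\n"
            "2024-01-01T00:01:00,10,30,0,0,19,5,5,12\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_mox_minutes(p)

    def test_non_monotone_timestamps_sorted_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.csv"
        p.write_text(
            "timestamp,IMA,sedentary_s,weight_bearing_s,standing_s,"
            "lpa_s,mpa_s,vpa_s,steps\n"
            "2024-01-01T00:05:00,0,60,0,0,0,0,0,0\n"
            "2024-01-01T00:01:00,0,60,0,0,0,0,0,0\n"
        )
        with caplog.at_level("WARNING", logger="ecoach"):
            records = read_mox_minutes(p)
        assert [r.timestamp.minute for r in records] == [1, 5]
        assert any("non-monotone" in r.message for r in caplog.records)

    def test_round_trip_on_generated_stream(self, tmp_path):
        from ecoach import SimulationConfig, simulate_minutes

        records = simulate_minutes(
            SimulationConfig(n_participants=1, n_days=1, seed=5))[:120]
        out = tmp_path / "m.csv"
        write_mox_minutes(records, out)
        assert read_mox_minutes(out) == records


class TestAggregation:
    def test_uniform_hour_and_day(self):
        minutes = [
            MinuteRecord(dt.datetime(2024, 1, 1, h, m), ima=100,
                         lpa_s=60, steps=1)
            for h in range(24) for m in range(60)
        ]
        hourly = aggregate_to_hourly(minutes)
        assert (hourly["steps"] == 60).all()
        assert (hourly["lpa_min"] == 60).all()
        daily = aggregate_to_daily(minutes, "P-1")
        row = daily.df.iloc[0]
        assert row.steps == 1440 and row.lpa_min == 1440

    def test_partition_day(self):
        minutes = [MinuteRecord(dt.datetime(2024, 1, 1, 0, m), ima=900, vpa_s=60)
                   for m in range(30)]
        minutes += [MinuteRecord(dt.datetime(2024, 1, 1, 1, m), ima=0,
                                 sedentary_s=60) for m in range(30)]
        daily = aggregate_to_daily(minutes, "P-1")
        assert daily.df.iloc[0].vpa_min == 30
        assert daily.df.iloc[0].sedentary_min == 30

    def test_daily_sums_match_brute_force(self):
        rng = np.random.default_rng(11)
        minutes = []
        for d in range(3):
            for i in range(200):
                split = rng.multinomial(60, [0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
                minutes.append(MinuteRecord(
                    dt.datetime(2024, 1, 1 + d) + dt.timedelta(minutes=int(i)),
                    ima=int(rng.integers(0, 1200)),
                    sedentary_s=int(split[0]), weight_bearing_s=int(split[1]),
                    standing_s=int(split[2]), lpa_s=int(split[3]),
                    mpa_s=int(split[4]), vpa_s=int(split[5]),
                    steps=int(rng.integers(0, 150)),
                ))
        daily = aggregate_to_daily(minutes, "P-1")
        # brute force: direct sums grouped by calendar date
        for _, row in daily.df.iterrows():
            todays = [m for m in minutes if m.timestamp.date() == row.date]
            assert row.steps == sum(m.steps for m in todays)
            assert row.lpa_min == sum(m.lpa_s for m in todays) // 60
            assert row.sedentary_min == sum(m.sedentary_s for m in todays) // 60

    def test_empty_input_gives_empty_dataset(self):
        assert len(aggregate_to_daily([], "P-1")) == 0


class TestImputation:
    def _dataset_with_gap(self):
        df = pd.DataFrame({
            "participant_id": ["A"] * 3,
            "date": [dt.date(2024, 1, d) for d in (1, 2, 3)],
            "steps": [1000.0, np.nan, 3000.0],
            "lpa_min": [10.0, 20.0, 30.0],
            "mpa_min": [1.0, 2.0, 3.0],
            "vpa_min": [0.0, 0.0, 0.0],
            "sedentary_min": [100.0, 100.0, 100.0],
        })
        return ActivityDataset(df)

    def test_two_point_mean(self):
        out = impute_missing(self._dataset_with_gap())
        assert out.df["steps"].tolist() == [1000, 2000, 3000]

    def test_identity_when_complete(self, labeled_cohort):
        ds, _ = labeled_cohort
        assert impute_missing(ds).df.drop(columns="steps").equals(
            ds.df.drop(columns="steps"))

    def test_imputed_values_equal_external_column_means(self):
        from ecoach import SimulationConfig, inject_missingness, simulate_daily

        ds, _ = simulate_daily(SimulationConfig(n_participants=4, n_days=25,
                                                seed=3))
        masked = inject_missingness(ds, rate=0.1, seed=9)
        out = impute_missing(masked)
        for pid, block in masked.df.groupby("participant_id"):
            res = out.df[out.df["participant_id"] == pid]
            for field in DAILY_FIELDS:
                holes = block[field].isna()
                if not holes.any():
                    continue
                expected = block.loc[~holes, field].mean()
                if field == "steps":
                    expected = round(expected)
                assert np.allclose(res.loc[holes[holes].index, field], expected)

    def test_fully_missing_field_is_an_error(self):
        ds = self._dataset_with_gap()
        df = ds.df.copy()
        df["mpa_min"] = np.nan
        with pytest.raises(ValueError, match="mpa_min.*'A'"):
            impute_missing(ActivityDataset(df))


def test_retention_filter_drops_short_participants():
    rows = []
    for pid, n in (("LONG", 31), ("SHORT", 5)):
        for d in range(n):
            rows.append(DailySummary(pid, dt.date(2024, 1, 1)
                                     + dt.timedelta(days=d), 1000))
    ds = ActivityDataset.from_summaries(rows)
    kept = filter_min_days(ds, min_days=30)
    assert kept.participants == ["LONG"]


def test_duplicate_dates_rejected_by_dataset():
    rows = [DailySummary("A", dt.date(2024, 1, 1), 1),
            DailySummary("A", dt.date(2024, 1, 1), 2)]
    with pytest.raises(ValueError, match="duplicate"):
        ActivityDataset.from_summaries(rows)
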