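import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from migrclass.geo import EARTH_RADIUS_KM, haversine_km
from migrclass.ingest import (
    average_daily,
    compute_nsd,
    read_gps_table,
    split_migratory_years,
)


class TestReadGpsTable:
    def test_header_only(self, fix_csv):
        path = fix_csv([])
        table = read_gps_table(path)
        assert len(table) == 0
        assert table.n_rejected == 0

    def test_single_row(self, fix_csv):
        path = fix_csv([("d1", "2016-01-01T00:00Z", 40.0, -111.0)])
        table = read_gps_table(path)
        assert len(table) == 1
        assert table.frame.loc[0, "lat"] == 40.0

    def test_corrupt_rows_counted(self, fix_csv):
        rows = []
        for a in ("a1", "a2", "a3"):
            for i in range(10):
                rows.append((a, f"2016-07-{i + 1:02d}T12:00Z", 40.0 + i * 0.01, -111.0))
        rows[3] = ("a1", "not-a-time", 40.0, -111.0)
        rows[17] = ("a2", "2016-07-08T12:00Z", 999.0, -111.0)
        path = fix_csv(rows)
        table = read_gps_table(path)
        assert len(table) == 28
        assert table.n_rejected == 2

    def test_missing_column_raises(self, fix_csv):
        path = fix_csv([("d1", "2016-01-01T00:00Z", 40.0, -111.0)],
                       columns=("id", "timestamp", "lat", "lon"))
        with pytest.raises(ValueError, match="missing column"):
            read_gps_table(path)

    def test_dialect_mapping(self, fix_csv):
        path = fix_csv([("d1", "2016-01-01T00:00Z", 40.0, -111.0)],
                       columns=("tag", "t", "y", "x"))
        table = read_gps_table(path, dialect={"animal_id": "tag", "timestamp": "t", "lat": "y", "lon": "x"})
        assert len(table) == 1

    def test_tsv_autodetect(self, tmp_path):
        path = tmp_path / "fixes.tsv"
        pd.DataFrame(
            [("d1", "2016-01-01T00:00Z", 40.0, -111.0)],
            columns=["animal_id", "timestamp", "lat", "lon"],
        ).to_csv(path, index=False, sep="\t")
        assert len(read_gps_table(path)) == 1


class TestAverageDaily:
    def test_one_fix_per_day_identity(self, fix_csv):
        path = fix_csv([("d1", f"2016-07-{i:02d}T06:00Z", 40.0 + i, -111.0) for i in range(1, 4)])
        daily = average_daily(read_gps_table(path))
        assert len(daily) == 3
        assert list(daily["lat"]) == [41.0, 42.0, 43.0]
        assert (daily["n_fixes"] == 1).all()

    def test_two_fix_mean(self, fix_csv):
        path = fix_csv(
            [
                ("d1", "2016-07-01T00:00Z", 40.0, -111.0),
                ("d1", "2016-07-01T12:00Z", 40.2, -111.2),
            ]
        )
        daily = average_daily(read_gps_table(path))
        assert len(daily) == 1
        assert daily.loc[0, "lat"] == pytest.approx(40.1)
        assert daily.loc[0, "lon"] == pytest.approx(-111.1)
        assert daily.loc[0, "n_fixes"] == 2

    def test_jittered_fixes_match_direct_mean(self, rng):
        # oracle: direct mean over the generated fixes
        lats = 40.0 + rng.normal(0, 0.01, size=48)
        lons = -111.0 + rng.normal(0, 0.01, size=48)
        frame = pd.DataFrame(
            {
                "animal_id": "d1",
                "timestamp": pd.to_datetime("2016-07-01", utc=True)
                + pd.to_timedelta(np.linspace(0, 23.5, 48), unit="h"),
                "lat": lats,
                "lon": lons,
            }
        )
        daily = average_daily(frame)
        assert len(daily) == 1
        assert daily.loc[0, "lat"] == pytest.approx(lats.mean(), abs=1e-12)
        assert daily.loc[0, "lon"] == pytest.approx(lons.mean(), abs=1e-12)

    def test_idempotent(self, rng):
        ts = pd.to_datetime("2016-07-01", utc=True) + pd.to_timedelta(rng.integers(0, 96, size=40) * 6, unit="h")
        frame = pd.DataFrame(
            {
                "animal_id": "d1",
                "timestamp": ts,
                "lat": 40 + rng.normal(0, 0.1, 40),
                "lon": -111 + rng.normal(0, 0.1, 40),
            }
        )
        once = average_daily(frame)
        again = average_daily(
            once.assign(timestamp=pd.to_datetime(once["date"]).dt.tz_localize("UTC"))
        )
        pd.testing.assert_frame_equal(
            once[["animal_id", "lat", "lon"]], again[["animal_id", "lat", "lon"]]
        )


class TestSplitMigratoryYears:
    def test_full_coverage_complete(self, full_year_daily):
        tracks = split_migratory_years(full_year_daily)
        assert len(tracks) == 1
        t = tracks[0]
        assert t.year_label == 2016
        assert t.complete
        assert len(t.core) == 365
        assert t.buffer_pre.empty and t.buffer_post.empty

    def test_half_year_incomplete(self, full_year_daily):
        half = full_year_daily[full_year_daily["date"] <= dt.date(2016, 12, 31)]
        tracks = split_migratory_years(half)
        assert len(tracks) == 1
        assert not tracks[0].complete

    def test_two_buffered_years(self):
        start, end = dt.date(2016, 6, 17), dt.date(2018, 7, 14)
        n = (end - start).days + 1
        daily = pd.DataFrame(
            {
                "animal_id": "d1",
                "date": [start + dt.timedelta(days=i) for i in range(n)],
                "lat": 40.0,
                "lon": -111.0,
                "n_fixes": 1,
            }
        )
        tracks = split_migratory_years(daily, buffer_days=14)
        complete = [t for t in tracks if t.complete]
        assert [t.year_label for t in complete] == [2016, 2017]
        for t in complete:
            assert len(t.buffer_pre) == 14
            assert len(t.buffer_post) == 14

    def test_gap_over_seven_days_incomplete(self, full_year_daily):
        gappy = full_year_daily[
            ~full_year_daily["date"].between(dt.date(2016, 10, 1), dt.date(2016, 10, 8))
        ]
        assert not split_migratory_years(gappy)[0].complete

    def test_split_concat_roundtrip(self, full_year_daily):
        tracks = split_migratory_years(full_year_daily)
        rebuilt = pd.concat([t.core for t in tracks], ignore_index=True)
        pd.testing.assert_frame_equal(rebuilt, full_year_daily.reset_index(drop=True))


class TestComputeNsd:
    def test_stationary_all_zero(self, full_year_daily):
        track = split_migratory_years(full_year_daily)[0]
        series = compute_nsd(track)
        assert np.allclose(series.values, 0.0)

    def test_reference_day_zero(self, full_year_daily):
        daily = full_year_daily.copy()
        daily.loc[daily.index[1:], "lat"] = 40.5
        series = compute_nsd(split_migratory_years(daily)[0])
        assert series.days.loc[series.days["date"] == dt.date(2016, 7, 1), "nsd_km2"].iloc[0] == 0.0

    def test_three_km_north(self, full_year_daily):
        # a point 3.000 km due north along the meridian: exact great circle
        daily = full_year_daily.copy()
        dlat = math.degrees(3.0 / EARTH_RADIUS_KM)
        daily.loc[daily.index[10], "lat"] = 40.0 + dlat
        series = compute_nsd(split_migratory_years(daily)[0])
        assert series.values[10] == pytest.approx(9.0, abs=1e-6)

    def test_incomplete_track_rejected(self, full_year_daily):
        half = full_year_daily[full_year_daily["date"] <= dt.date(2016, 12, 31)]
        track = split_migratory_years(half)[0]
        with pytest.raises(ValueError):
            compute_nsd(track)

    def test_displacement_matches_haversine_oracle(self, full_year_daily, rng):
        daily = full_year_daily.copy()
        daily["lat"] = 40.0 + rng.normal(0, 0.05, len(daily))
        daily["lon"] = -111.0 + rng.normal(0, 0.05, len(daily))
        daily = daily.sort_values("date").reset_index(drop=True)
        series = compute_nsd(split_migratory_years(daily)[0])
        ref = daily.loc[daily["date"] == dt.date(2016, 7, 1)].iloc[0]
        expect = haversine_km(ref["lat"], ref["lon"], daily["lat"].to_numpy(), daily["lon"].to_numpy())
        np.testing.assert_allclose(series.days["displacement_km"], expect, atol=1e-9)

    def test_invariant_under_relabel_and_time_offset(self, full_year_daily):
        daily = full_year_daily.copy()
        daily.loc[daily.index[5:], "lon"] = -110.8
        base = compute_nsd(split_migratory_years(daily)[0]).values
        relabeled = daily.assign(animal_id="other")
        assert np.allclose(compute_nsd(split_migratory_years(relabeled)[0]).values, base)
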