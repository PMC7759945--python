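"""Independence filtering, station retention and diel classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dielcam import duikerdata
from dielcam.events import (
    DielSummary,
    EmptyResultError,
    EventSeries,
    SolarSchedule,
    classify_diel,
    event_series,
    filter_independent_events,
    read_detections,
    retain_informative_stations,
)
from dielcam._util import hours_to_radians


def _records(rows):
    df = pd.DataFrame(rows, columns=["site", "station", "species", "datetime", "count"])
    df["datetime"] = pd.to_datetime(df["datetime"])
    return df


class TestIndependenceFilter:
    @pytest.mark.parametrize(
        "minutes_apart,expected_events",
        [(30, 1), (59, 1), (60, 2), (61, 2)],
        ids=["30min", "59min", "60min-boundary", "61min"],
    )
    def test_one_hour_rule(self, minutes_apart, expected_events):
        rows = [
            ("A", "A-1", "sp", "2020-01-01 10:00", 1),
            ("A", "A-1", "sp", f"2020-01-01 10:{0:02d}", 1),
        ]
        df = _records(rows)
        df.loc[1, "datetime"] = pd.Timestamp("2020-01-01 10:00") + pd.Timedelta(minutes=minutes_apart)
        assert len(filter_independent_events(df)) == expected_events

    def test_window_compares_to_last_retained_event(self):
        # 10:00, 10:40, 11:20: middle dropped, 11:20 kept only if >= 1 h
        # after the *retained* 10:00 record, which it is
        df = _records([
            ("A", "A-1", "sp", "2020-01-01 10:00", 1),
            ("A", "A-1", "sp", "2020-01-01 10:40", 1),
            ("A", "A-1", "sp", "2020-01-01 11:20", 1),
        ])
        kept = filter_independent_events(df)
        assert list(kept["datetime"].dt.strftime("%H:%M")) == ["10:00", "11:20"]

    def test_species_and_stations_filtered_separately(self):
        df = _records([
            ("A", "A-1", "sp1", "2020-01-01 10:00", 1),
            ("A", "A-1", "sp2", "2020-01-01 10:10", 1),  # two-species photo pair
            ("A", "A-2", "sp1", "2020-01-01 10:20", 1),  # other station
        ])
        assert len(filter_independent_events(df)) == 3

    def test_multi_individual_photo_is_one_event(self):
        df = _records([("A", "A-1", "sp", "2020-01-01 10:00", 3)])
        kept = filter_independent_events(df)
        assert len(kept) == 1

    def test_idempotent(self, rng):
        ts = pd.Timestamp("2020-01-01") + pd.to_timedelta(
            np.sort(rng.uniform(0, 72 * 60, 200)), unit="m"
        )
        df = _records([("A", f"A-{i % 3}", "sp", t, 1) for i, t in enumerate(ts)])
        once = filter_independent_events(df)
        twice = filter_independent_events(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_window_keeps_every_photo(self, rng):
        ts = pd.Timestamp("2020-01-01") + pd.to_timedelta(rng.integers(0, 5000, 50), unit="m")
        df = _records([("A", "A-1", "sp", t, 1) for t in ts])
        assert len(filter_independent_events(df, window_minutes=0)) == len(df)

    def test_filtered_count_never_exceeds_raw(self, rng):
        ts = pd.Timestamp("2020-01-01") + pd.to_timedelta(rng.integers(0, 3000, 120), unit="m")
        df = _records([("A", f"A-{i % 4}", f"sp{i % 2}", t, 1) for i, t in enumerate(ts)])
        assert len(filter_independent_events(df)) <= len(df)

    def test_unparseable_timestamp_rejected_with_warning(self, tmp_path, caplog):
        path = tmp_path / "r.csv"
        path.write_text(
            "site,station,species,datetime,count\n"
            "A,A-1,sp,2020-01-01 10:00,1\n"
            "A,A-1,sp,not-a-date,1\n"
        )
        with caplog.at_level("WARNING"):
            df = read_detections(path)
        assert len(df) == 1
        assert "unparseable" in caplog.text

    def test_published_census_reconstruction_matches_totals(self):
        """A record table generated from the published site x species census
        filters back to the exact published totals (bursts removed)."""
        records = duikerdata.events_from_counts(seed=3)
        filtered = filter_independent_events(records)
        totals = filtered.groupby("species").size()
        expected = duikerdata.site_species_table().sum(axis=0)
        for sp, n in expected.items():
            assert totals.get(sp, 0) == n
        assert len(filtered) == 4358
        assert len(records) > len(filtered)  # bursts exercised the filter


class TestStationRetention:
    def test_published_ratio(self):
        ev = _records([("A", f"st{i}", "sp", "2020-01-01 10:00", 1) for i in range(315)])
        kept, pct = retain_informative_stations(ev, 428)
        assert len(kept) == 315
        assert pct == 73.6

    def test_half_kept(self):
        ev = _records([("A", "st0", "sp", "2020-01-01 10:00", 1)])
        _, pct = retain_informative_stations(ev, 2)
        assert pct == 50.0

    def test_empty_events_error(self):
        ev = _records([]) if False else pd.DataFrame(columns=["station"])
        with pytest.raises(EmptyResultError):
            retain_informative_stations(ev, 10)


class TestDielClassification:
    def _series(self, hours):
        return EventSeries("sp", hours_to_radians(np.asarray(hours, dtype=float)))

    def test_sunrise_inclusive_sunset_exclusive(self):
        s = classify_diel(self._series([6.0, 17.99, 18.0, 5.99]))
        assert s.n_diurnal == 2 and s.n_nocturnal == 2

    def test_twilight_straddles_boundaries(self):
        s = classify_diel(self._series([5.5, 6.5, 17.5, 18.5, 12.0]))
        assert s.n_twilight == 4
        assert s.n_diurnal + s.n_nocturnal == s.n_total

    @pytest.mark.parametrize(
        "n_total,n_principal,nocturnal_principal,pct,category",
        [
            (2562, 2474, False, 97, "strongly_diurnal"),
            (469, 465, True, 99, "strongly_nocturnal"),
            (279, 236, True, 85, "mostly_nocturnal"),
            (945, 816, False, 86, "mostly_diurnal"),
            (61, 55, False, 90, "strongly_diurnal"),
            (42, 33, False, 79, "mostly_diurnal"),
        ],
    )
    def test_published_counts_reproduce_categories(
        self, n_total, n_principal, nocturnal_principal, pct, category
    ):
        kw = {"n_nocturnal" if nocturnal_principal else "n_diurnal": n_principal}
        s = DielSummary.from_counts("sp", n_total, **kw)
        principal_pct = s.pct_nocturnal if nocturnal_principal else s.pct_diurnal
        assert principal_pct == pct
        assert s.category == category

    def test_boundary_fractions(self):
        assert DielSummary.from_counts("sp", 100, n_nocturnal=10).category == "strongly_diurnal"
        assert DielSummary.from_counts("sp", 100, n_nocturnal=90).category == "strongly_nocturnal"
        assert DielSummary.from_counts("sp", 100, n_nocturnal=50).category == "cathemeral"

    def test_twilight_percentage_uses_total(self):
        s = DielSummary.from_counts("sp", 2562, n_diurnal=2474, n_twilight=666)
        assert s.pct_twilight == 26

    def test_empty_series_error(self):
        with pytest.raises(EmptyResultError):
            classify_diel(EventSeries("sp", np.empty(0)))

    @given(st.lists(st.floats(0, 23.999), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_day_night_partition_is_exhaustive(self, hours):
        s = classify_diel(self._series(hours))
        assert s.n_diurnal + s.n_nocturnal == s.n_total
        assert abs(s.pct_diurnal + s.pct_nocturnal - 100) <= 1  # integer rounding


class TestSolarSchedule:
    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            SolarSchedule(sunrise=19, sunset=18)
        with pytest.raises(ValueError):
            SolarSchedule(twilight_halfwidth=0)
        with pytest.raises(ValueError):
            SolarSchedule(sunrise=11, sunset=13, twilight_halfwidth=2)


def test_event_series_roundtrip():
    df = _records([
        ("A", "A-1", "sp1", "2020-01-01 06:30", 1),
        ("A", "A-2", "sp1", "2020-01-01 18:15", 1),
        ("A", "A-1", "sp2", "2020-01-01 12:00", 1),
    ])
    series = event_series(df)
    assert set(series) == {"sp1", "sp2"}
    np.testing.assert_allclose(series["sp1"].hours, [6.5, 18.25])
    assert list(series["sp1"].station_ids) == ["A-1", "A-2"]
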