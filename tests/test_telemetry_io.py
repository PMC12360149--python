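"""I/O and cleaning-cascade tests."""

import numpy as np
import pandas as pd
import pytest

from troutline import telemetry_io as tio


def brute_force_spurious(det, window_h=1.0):
    """Independent oracle: O(n^2) +/- window neighbour scan."""
    keep = []
    w = pd.Timedelta(hours=window_h)
    for i, row in det.iterrows():
        others = det[
            (det["tag_id"] == row["tag_id"])
            & (det["receiver_id"] == row["receiver_id"])
            & (det.index != i)
        ]
        near = (others["timestamp"] - row["timestamp"]).abs() <= w
        keep.append(bool(near.any()))
    return det[np.array(keep)]


def make_fish(rows):
    recs = []
    for fid, tag, origin, ttype, cap_date, length in rows:
        recs.append(
            {
                "fish_id": fid,
                "tag_id": tag,
                "origin": origin,
                "transmitter_type": ttype,
                "capture_date": pd.Timestamp(cap_date),
                "capture_length": length,
                "capture_method": "angling",
                "capture_region": "A",
            }
        )
    return pd.DataFrame(recs)


class TestReadWrite:
    def test_well_formed_sorted(self, tmp_path, det_factory):
        det = det_factory(
            [
                ("B", "R1", "2021-01-01T10:00:00"),
                ("A", "R1", "2021-01-01T12:00:00"),
                ("A", "R2", "2021-01-01T11:00:00"),
            ]
        )
        p = tmp_path / "d.csv"
        tio.write_detections(det, p)
        got = tio.read_detections(p)
        assert len(got) == 3
        assert got["tag_id"].tolist() == ["A", "A", "B"]
        assert got.groupby("tag_id")["timestamp"].is_monotonic_increasing.all()

    def test_unparseable_timestamp_skipped(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "tag_id,receiver_id,timestamp,depth,temperature\n"
            "A,R1,2021-01-01T10:00:00Z,,\n"
            "A,R1,not-a-time,,\n"
            "A,R1,2021-01-01T11:00:00Z,,\n"
        )
        got = tio.read_detections(p)
        assert len(got) == 2

    def test_missing_column_hard_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("tag_id,timestamp\nA,2021-01-01T10:00:00Z\n")
        with pytest.raises(ValueError, match="receiver_id"):
            tio.read_detections(p)

    def test_round_trip(self, tmp_path, det_factory):
        det = det_factory(
            [
                ("A", "R1", "2021-01-01T10:00:00", 12.5, 6.0),
                ("A", "R2", "2021-03-02T11:30:15", 40.0, 4.5),
            ]
        )
        p = tmp_path / "d.csv"
        tio.write_detections(det, p)
        got = tio.read_detections(p)
        pd.testing.assert_frame_equal(got, det)


class TestFilterSpurious:
    def test_isolated_single_removed(self, det_factory):
        det = det_factory(
            [
                ("A", "R1", "2021-01-01T00:00:00"),
                ("A", "R1", "2021-01-02T00:00:00"),
                ("A", "R1", "2021-01-02T00:30:00"),
            ]
        )
        out, report = tio.filter_spurious(det)
        assert report.removed["spurious"] == 1
        assert out["timestamp"].min() == pd.Timestamp("2021-01-02T00:00:00", tz="UTC")

    def test_pair_within_window_kept(self, det_factory):
        det = det_factory(
            [
                ("A", "R1", "2021-01-01T00:00:00"),
                ("A", "R1", "2021-01-01T00:30:00"),
            ]
        )
        out, report = tio.filter_spurious(det)
        assert len(out) == 2 and report.removed["spurious"] == 0

    def test_three_point_example_matches_oracle(self, det_factory):
        det = det_factory(
            [
                ("A", "R1", "2021-01-01T00:00:00"),
                ("A", "R1", "2021-01-01T02:00:00"),
                ("A", "R1", "2021-01-01T02:30:00"),
            ]
        )
        out, _ = tio.filter_spurious(det)
        expected = brute_force_spurious(det)
        assert len(out) == 2
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), expected.reset_index(drop=True)
        )

    def test_same_tag_other_receiver_does_not_rescue(self, det_factory):
        det = det_factory(
            [
                ("A", "R1", "2021-01-01T00:00:00"),
                ("A", "R2", "2021-01-01T00:10:00"),
                ("A", "R2", "2021-01-01T00:20:00"),
            ]
        )
        out, _ = tio.filter_spurious(det)
        assert ("R1" not in out["receiver_id"].values)

    def test_random_table_matches_oracle(self, det_factory):
        rng = np.random.default_rng(42)
        rows = [
            (
                f"T{rng.integers(2)}",
                f"R{rng.integers(3)}",
                pd.Timestamp("2021-01-01", tz="UTC")
                + pd.Timedelta(minutes=int(rng.integers(0, 3000))),
            )
            for _ in range(60)
        ]
        det = (
            pd.DataFrame(rows, columns=["tag_id", "receiver_id", "timestamp"])
            .assign(depth=np.nan, temperature=np.nan)
            .sort_values(["tag_id", "timestamp"], kind="mergesort")
            .reset_index(drop=True)
        )
        out, _ = tio.filter_spurious(det)
        expected = brute_force_spurious(det)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), expected.reset_index(drop=True)
        )

    def test_idempotent(self, det_factory):
        det = det_factory(
            [
                ("A", "R1", "2021-01-01T00:00:00"),
                ("A", "R1", "2021-01-01T02:00:00"),
                ("A", "R1", "2021-01-01T02:30:00"),
                ("B", "R2", "2021-01-05T00:00:00"),
            ]
        )
        once, _ = tio.filter_spurious(det)
        twice, rep = tio.filter_spurious(once)
        assert rep.removed["spurious"] == 0
        pd.testing.assert_frame_equal(once, twice)


class TestFlagDead:
    def test_constant_depth_sensor_flagged(self, det_factory):
        rng = np.random.default_rng(1)
        rows = [
            ("A", "R1", pd.Timestamp("2021-01-01", tz="UTC") + pd.Timedelta(hours=h),
             41.0 + rng.normal(0, 0.2))
            for h in range(48)
        ]
        det = pd.DataFrame(
            rows, columns=["tag_id", "receiver_id", "timestamp", "depth"]
        ).assign(temperature=np.nan)
        fish = make_fish([("F1", "A", "stocked", "sensor", "2020-10-01", 420.0)])
        flagged, rep = tio.flag_dead(det, fish, residency_days=9999)
        assert flagged == ["A"]

    def test_alternating_stations_not_flagged(self, det_factory):
        rows = []
        for d in range(60):
            rows.append(("A", f"R{d % 3}", f"2021-01-{1 + d % 28:02d}T00:00:00"))
        det = det_factory(rows)
        fish = make_fish([("F1", "A", "wild", "plain", "2020-10-01", 600.0)])
        flagged, _ = tio.flag_dead(det, fish)
        assert flagged == []

    def test_terminal_residency_flagged(self, det_factory):
        rows = []
        start = pd.Timestamp("2021-01-01", tz="UTC")
        for d in range(100):  # mobile phase
            rows.append(("A", f"R{d % 4}", start + pd.Timedelta(days=d)))
        for d in range(100, 145):  # parked at R7 for the final 45 days
            rows.append(("A", "R7", start + pd.Timedelta(days=d)))
        det = pd.DataFrame(rows, columns=["tag_id", "receiver_id", "timestamp"]).assign(
            depth=np.nan, temperature=np.nan
        )
        fish = make_fish([("F1", "A", "wild", "plain", "2020-10-01", 600.0)])
        flagged, _ = tio.flag_dead(det, fish, residency_days=30)
        assert flagged == ["A"]
        flagged60, _ = tio.flag_dead(det, fish, residency_days=60)
        assert flagged60 == []

    def test_station_mapping_used(self, det_factory):
        # two receivers at the same station count as one station
        rows = [
            ("A", ["R1", "R2"][d % 2], f"2021-0{1 + d // 28}-{1 + d % 28:02d}T00:00:00")
            for d in range(40)
        ]
        det = det_factory(rows)
        fish = make_fish([("F1", "A", "wild", "plain", "2020-10-01", 600.0)])
        receivers = pd.DataFrame(
            {"receiver_id": ["R1", "R2"], "station_id": ["S1", "S1"]}
        )
        flagged, _ = tio.flag_dead(det, fish, receivers=receivers, residency_days=30)
        assert flagged == ["A"]


class TestCohortFilters:
    def test_release_season_removed(self, det_factory, simple_calendar):
        det = det_factory(
            [
                ("A", "R1", "2021-08-01T00:00:00"),  # summer (release season)
                ("A", "R1", "2021-10-01T00:00:00"),  # fall start
                ("A", "R1", "2021-12-31T00:00:00"),  # fall end day
            ]
        )
        fish = make_fish([("F1", "A", "stocked", "plain", "2021-07-15", 400.0)])
        out, rep = tio.apply_cohort_filters(det, fish, simple_calendar)
        assert rep.removed["release_season"] == 1
        assert len(out) == 2
        assert (out["timestamp"] >= pd.Timestamp("2021-10-01", tz="UTC")).all()

    def test_release_season_only_fish_dropped(self, det_factory, simple_calendar):
        det = det_factory(
            [
                ("A", "R1", "2021-08-01T00:00:00"),
                ("A", "R1", "2021-09-01T00:00:00"),
            ]
        )
        fish = make_fish([("F1", "A", "stocked", "plain", "2021-07-15", 400.0)])
        out, rep = tio.apply_cohort_filters(det, fish, simple_calendar)
        assert out.empty

    def test_window_clip_counts(self, det_factory, simple_calendar):
        det = det_factory(
            [
                ("A", "R1", "2021-01-15T00:00:00"),  # release season (winter)
                ("A", "R1", "2021-04-01T00:00:00"),  # spring start
                ("A", "R1", "2021-05-15T00:00:00"),
                ("A", "R1", "2021-06-30T00:00:00"),  # spring final day
                ("A", "R1", "2021-12-15T00:00:00"),  # outside window
            ]
        )
        fish = make_fish([("F1", "A", "stocked", "plain", "2021-01-05", 400.0)])
        out, rep = tio.apply_cohort_filters(
            det,
            fish,
            simple_calendar,
            window=("2021-02-01", "2021-11-01"),
        )
        assert rep.removed["release_season"] == 1
        assert rep.removed["window"] == 1
        assert rep.removed["full_season_coverage"] == 0
        assert len(out) == 3

    def test_capture_outside_calendar_errors(self, det_factory, simple_calendar):
        det = det_factory([("A", "R1", "2021-08-01T00:00:00")])
        fish = make_fish([("F1", "A", "stocked", "plain", "2019-01-01", 400.0)])
        with pytest.raises(ValueError, match="outside season calendar"):
            tio.apply_cohort_filters(det, fish, simple_calendar)

    def test_full_season_coverage_required(self, det_factory, simple_calendar):
        # fish B spans all of fall; fish C only half of fall
        det = det_factory(
            [
                ("B", "R1", "2021-10-01T00:00:00"),
                ("B", "R1", "2021-12-31T12:00:00"),
                ("C", "R1", "2021-10-20T00:00:00"),
                ("C", "R1", "2021-11-20T00:00:00"),
            ]
        )
        fish = make_fish(
            [
                ("F2", "B", "stocked", "plain", "2021-08-01", 400.0),
                ("F3", "C", "wild", "plain", "2021-08-01", 400.0),
            ]
        )
        out, rep = tio.apply_cohort_filters(det, fish, simple_calendar)
        assert set(out["tag_id"]) == {"B"}
        assert rep.dropped_fish == ["C"]


class TestCascadeProperties:
    def test_idempotent_and_value_preserving(self, det_factory, simple_calendar):
        rng = np.random.default_rng(7)
        rows = []
        for d in range(120):
            rows.append(
                (
                    "A",
                    f"R{rng.integers(3)}",
                    pd.Timestamp("2021-04-02", tz="UTC")
                    + pd.Timedelta(minutes=int(rng.integers(0, 250_000))),
                )
            )
        det = (
            pd.DataFrame(rows, columns=["tag_id", "receiver_id", "timestamp"])
            .assign(depth=np.nan, temperature=np.nan)
            .sort_values(["tag_id", "timestamp"], kind="mergesort")
            .reset_index(drop=True)
        )
        fish = make_fish([("F1", "A", "stocked", "plain", "2021-02-01", 420.0)])
        once, rep1 = tio.clean_cascade(det, fish, simple_calendar)
        twice, rep2 = tio.clean_cascade(once, fish, simple_calendar)
        pd.testing.assert_frame_equal(once.reset_index(drop=True), twice.reset_index(drop=True))
        # surviving rows appear unchanged and in the original order
        merged = det.merge(once, how="inner")
        assert len(merged) == len(once)
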