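"""Detection / receiver / fish table I/O and the data-cleaning cascade.

The cascade runs in a fixed order: spurious-single removal, dead-fish
flagging, then cohort filters (release-season removal, study-window
clip, full-season coverage).  Filters never reorder surviving rows and
never alter field values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ThresholdsConfig

__all__ = [
    "FilterReport",
    "read_detections",
    "write_detections",
    "read_receivers",
    "read_fish",
    "filter_spurious",
    "flag_dead",
    "apply_cohort_filters",
    "clean_cascade",
]

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["tag_id", "receiver_id", "timestamp", "depth", "temperature"]
FISH_COLUMNS = [
    "fish_id",
    "tag_id",
    "origin",
    "transmitter_type",
    "capture_date",
    "capture_length",
    "capture_method",
    "capture_region",
]
ORIGINS = {"stocked", "wild"}
TRANSMITTER_TYPES = {"sensor", "plain"}


@dataclass
class FilterReport:
    """Bookkeeping for one or more filtering steps."""

    input_rows: int = 0
    output_rows: int = 0
    removed: dict = field(default_factory=dict)  # rule -> rows removed
    dead_fish: list = field(default_factory=list)
    dropped_fish: list = field(default_factory=list)

    @property
    def removed_fraction(self) -> dict:
        if self.input_rows == 0:
            return {k: 0.0 for k in self.removed}
        return {k: v / self.input_rows for k, v in self.removed.items()}

    def check(self) -> None:
        if sum(self.removed.values()) != self.input_rows - self.output_rows:
            raise AssertionError("filter report does not balance")

    def merge(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport(
            input_rows=self.input_rows or other.input_rows,
            output_rows=other.output_rows,
            removed={**self.removed},
            dead_fish=self.dead_fish + other.dead_fish,
            dropped_fish=self.dropped_fish + other.dropped_fish,
        )
        for k, v in other.removed.items():
            out.removed[k] = out.removed.get(k, 0) + v
        return out


# ---------------------------------------------------------------------------
# I/O


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV; rows sorted by (tag, time), bad rows skipped."""
    df = pd.read_csv(path, dtype={"tag_id": str, "receiver_id": str})
    for col in ("tag_id", "receiver_id", "timestamp"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna() | df["tag_id"].isna() | df["receiver_id"].isna()
    if bad.any():
        log.warning("skipped %d malformed detection rows", int(bad.sum()))
    df = df.loc[~bad].assign(timestamp=ts[~bad])
    for col in ("depth", "temperature"):
        if col not in df.columns:
            df[col] = np.nan
        else:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["depth"] < 0).any():
        raise ValueError("negative depth in detections")
    return (
        df[DETECTION_COLUMNS]
        .sort_values(["tag_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_detections(detections: pd.DataFrame, path) -> None:
    out = detections.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z"
    )
    out.to_csv(path, index=False)


def read_receivers(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        parse_dates=["deploy_start", "deploy_end"],
        dtype={"receiver_id": str, "station_id": str},
    )
    for col in ("receiver_id", "station_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    for col in ("deploy_start", "deploy_end"):
        if col in df.columns and df[col].dt.tz is None:
            df[col] = df[col].dt.tz_localize("UTC")
    return df


def read_fish(path) -> pd.DataFrame:
    df = pd.read_csv(df_path := path, parse_dates=["capture_date"], dtype={"tag_id": str})
    for col in FISH_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    if (df["capture_length"] <= 0).any():
        raise ValueError("capture_length must be positive")
    if not set(df["origin"]).issubset(ORIGINS):
        raise ValueError(f"unknown origin values in {df_path}")
    if not set(df["transmitter_type"]).issubset(TRANSMITTER_TYPES):
        raise ValueError(f"unknown transmitter_type values in {df_path}")
    return df


# ---------------------------------------------------------------------------
# Cleaning cascade


def filter_spurious(
    detections: pd.DataFrame, window_h: float = 1.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop detections with no same-tag same-receiver neighbour within
    +/- ``window_h`` hours.

    A detection is spurious iff it is isolated at its receiver over a
    period longer than the window on both sides.
    """
    report = FilterReport(input_rows=len(detections))
    if detections.empty:
        report.output_rows = 0
        report.removed["spurious"] = 0
        return detections, report
    window_ns = int(pd.Timedelta(hours=window_h).value)
    keep = np.zeros(len(detections), dtype=bool)
    order = detections.reset_index(drop=True).sort_values(
        ["tag_id", "receiver_id", "timestamp"], kind="mergesort"
    )
    pos = order.index.to_numpy()
    ts = pd.DatetimeIndex(order["timestamp"]).asi8
    same = (
        (order["tag_id"].to_numpy()[1:] == order["tag_id"].to_numpy()[:-1])
        & (order["receiver_id"].to_numpy()[1:] == order["receiver_id"].to_numpy()[:-1])
    )
    gap_ok = (ts[1:] - ts[:-1]) <= window_ns
    near = same & gap_ok
    keep_sorted = np.zeros(len(order), dtype=bool)
    keep_sorted[:-1] |= near
    keep_sorted[1:] |= near
    keep[pos] = keep_sorted
    out = detections.iloc[np.flatnonzero(keep)]
    report.output_rows = len(out)
    report.removed["spurious"] = int((~keep).sum())
    report.check()
    return out.reset_index(drop=True), report


def flag_dead(
    detections: pd.DataFrame,
    fish: pd.DataFrame,
    receivers: pd.DataFrame | None = None,
    residency_days: float = 30.0,
    depth_sd_m: float = 1.0,
) -> tuple[list, FilterReport]:
    """Flag dead fish.

    Rule (a): sensor-tagged fish whose overall depth standard deviation
    is below ``depth_sd_m``.  Rule (b): the final run of detections sits
    at a single station continuously for >= ``residency_days`` up to the
    end of the fish's record.  Returns flagged tag ids.
    """
    report = FilterReport(input_rows=len(detections))
    station_of = None
    if receivers is not None:
        station_of = receivers.set_index("receiver_id")["station_id"].to_dict()
    flagged = []
    sensor_tags = set(fish.loc[fish["transmitter_type"] == "sensor", "tag_id"])
    for tag, grp in detections.groupby("tag_id", sort=False):
        grp = grp.sort_values("timestamp", kind="mergesort")
        reason = None
        if tag in sensor_tags:
            depths = grp["depth"].dropna()
            if len(depths) >= 2 and depths.std(ddof=1) < depth_sd_m:
                reason = "depth_sd"
        if reason is None and len(grp) >= 2:
            stations = (
                grp["receiver_id"].map(station_of)
                if station_of
                else grp["receiver_id"]
            ).to_numpy()
            last = stations[-1]
            run_start = len(stations)
            for i in range(len(stations) - 1, -1, -1):
                if stations[i] != last:
                    break
                run_start = i
            ts = pd.DatetimeIndex(grp["timestamp"])
            span = (ts[-1] - ts[run_start]).total_seconds() / 86400.0
            if span >= residency_days:
                reason = "terminal_residency"
        if reason is not None:
            flagged.append(tag)
    report.dead_fish = flagged
    report.output_rows = len(detections)
    report.removed["dead"] = 0
    return flagged, report


def drop_dead(
    detections: pd.DataFrame, flagged: list
) -> tuple[pd.DataFrame, FilterReport]:
    report = FilterReport(input_rows=len(detections))
    keep = ~detections["tag_id"].isin(flagged)
    out = detections.loc[keep].reset_index(drop=True)
    report.output_rows = len(out)
    report.removed["dead"] = int((~keep).sum())
    report.dead_fish = list(flagged)
    report.check()
    return out, report


def apply_cohort_filters(
    detections: pd.DataFrame,
    fish: pd.DataFrame,
    calendar,
    window: tuple | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Release-season removal, window clip and full-season coverage.

    * removes each fish's detections inside the season interval holding
      its capture date;
    * clips to the half-open study window [start, end);
    * drops fish whose detection span does not contain at least one
      complete season interval.
    """
    report = FilterReport(input_rows=len(detections))
    ts = pd.DatetimeIndex(detections["timestamp"])
    naive = ts.tz_localize(None) if ts.tz is not None else ts

    release_mask = np.zeros(len(detections), dtype=bool)
    tag_arr = detections["tag_id"].to_numpy()
    for _, fr in fish.iterrows():
        cap = pd.Timestamp(fr["capture_date"])
        if cap.tz is not None:
            cap = cap.tz_localize(None)
        interval = calendar.interval_containing(cap)
        if interval is None:
            raise ValueError(
                f"fish {fr['fish_id']} capture date {cap} outside season calendar"
            )
        in_season = (naive >= interval["start"]) & (naive < interval["end"])
        release_mask |= (tag_arr == fr["tag_id"]) & np.asarray(in_season)
    removed_release = int(release_mask.sum())

    keep = ~release_mask
    if window is not None:
        w0, w1 = (pd.Timestamp(w) for w in window)
        w0 = w0.tz_localize(None) if w0.tz else w0
        w1 = w1.tz_localize(None) if w1.tz else w1
        in_window = np.asarray((naive >= w0) & (naive < w1))
        removed_window = int((keep & ~in_window).sum())
        keep &= in_window
    else:
        removed_window = 0

    surv = detections.loc[keep]
    surv_naive = naive[keep]
    iv = calendar.intervals
    dropped = []
    keep_fish = np.ones(len(surv), dtype=bool)
    for tag, grp_idx in surv.groupby("tag_id", sort=False).indices.items():
        t = surv_naive[grp_idx]
        lo, hi = t.min(), t.max()
        # a season counts as fully covered when the detection span reaches
        # from its start through its final day (end is exclusive)
        covered = (
            (iv["start"] >= lo) & (iv["end"] - pd.Timedelta(days=1) <= hi)
        ).any()
        if not covered:
            dropped.append(tag)
            keep_fish[grp_idx] = False
    removed_coverage = int((~keep_fish).sum())
    out = surv.loc[keep_fish].reset_index(drop=True)

    report.output_rows = len(out)
    report.removed = {
        "release_season": removed_release,
        "window": removed_window,
        "full_season_coverage": removed_coverage,
    }
    report.dropped_fish = dropped
    report.check()
    return out, report


def clean_cascade(
    detections: pd.DataFrame,
    fish: pd.DataFrame,
    calendar,
    window: tuple | None = None,
    receivers: pd.DataFrame | None = None,
    thresholds: ThresholdsConfig = ThresholdsConfig(),
) -> tuple[pd.DataFrame, FilterReport]:
    """Full cleaning cascade in the fixed rule order."""
    d1, r1 = filter_spurious(detections, thresholds.spurious_window_h)
    flagged, _ = flag_dead(
        d1,
        fish,
        receivers,
        residency_days=thresholds.dead_residency_days,
        depth_sd_m=thresholds.dead_depth_sd_m,
    )
    d2, r2 = drop_dead(d1, flagged)
    d3, r3 = apply_cohort_filters(d2, fish, calendar, window)
    return d3, r1.merge(r2).merge(r3)
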