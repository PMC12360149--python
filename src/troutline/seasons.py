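"""Biological-season derivation from temperature series.

Seasons are defined by a deterministic state machine over the smoothed
daily near-surface temperature:

* winter -> spring when T >= spring onset (default 8 degC)
* spring -> summer when T > summer onset (default 17 degC)
* summer -> fall  when T < fall onset (default 15 degC)
* fall   -> winter when T < spring onset (default 8 degC)

Boundary conventions keep the printed ranges: 8 degC belongs to spring,
17 degC to spring, 15 degC to summer, 8 degC to fall.  If the series
never reaches the summer onset the year has no summer and spring closes
directly into winter when T drops below the spring onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ThresholdsConfig

__all__ = [
    "SeasonCalendar",
    "daily_experienced",
    "smooth",
    "classify_seasons",
    "stratification_breakpoints",
]

SEASON_ORDER = ("winter", "spring", "summer", "fall")


@dataclass
class SeasonCalendar:
    """Ordered, contiguous, half-open [start, end) season intervals."""

    intervals: pd.DataFrame  # columns: start, end, label (Timestamps, tz-naive dates ok)
    thresholds: ThresholdsConfig = field(default_factory=ThresholdsConfig)

    def __post_init__(self) -> None:
        iv = self.intervals.reset_index(drop=True)
        iv["start"] = pd.to_datetime(iv["start"])
        iv["end"] = pd.to_datetime(iv["end"])
        if (iv["end"] <= iv["start"]).any():
            raise ValueError("empty or inverted season interval")
        if len(iv) > 1:
            gaps = iv["start"].iloc[1:].to_numpy() != iv["end"].iloc[:-1].to_numpy()
            if gaps.any():
                raise ValueError("season intervals must be contiguous")
        bad = ~iv["label"].isin(SEASON_ORDER)
        if bad.any():
            raise ValueError(f"unknown season labels: {iv['label'][bad].unique()}")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def start(self) -> pd.Timestamp:
        return self.intervals["start"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.intervals["end"].iloc[-1]

    def label_times(self, times) -> np.ndarray:
        """Season label for each timestamp (None outside the calendar)."""
        t = pd.DatetimeIndex(times)
        if t.tz is not None:
            t = t.tz_localize(None)
        starts = self.intervals["start"].to_numpy()
        idx = np.searchsorted(starts, t.to_numpy(), side="right") - 1
        labels = self.intervals["label"].to_numpy()
        ends = self.intervals["end"].to_numpy()
        out = np.full(len(t), None, dtype=object)
        ok = (idx >= 0) & (t.to_numpy() < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = labels[idx[ok]]
        return out

    def season_instances(self, times) -> pd.DataFrame:
        """(label, year, start, end) per interval; year = start's year."""
        iv = self.intervals
        return pd.DataFrame(
            {
                "label": iv["label"],
                "year": iv["start"].dt.year,
                "start": iv["start"],
                "end": iv["end"],
            }
        )

    def instance_of_times(self, times) -> pd.DataFrame:
        """Map timestamps to (label, year) season instances."""
        t = pd.DatetimeIndex(times)
        if t.tz is not None:
            t = t.tz_localize(None)
        starts = self.intervals["start"].to_numpy()
        idx = np.searchsorted(starts, t.to_numpy(), side="right") - 1
        ends = self.intervals["end"].to_numpy()
        ok = (idx >= 0) & (t.to_numpy() < ends[np.clip(idx, 0, len(ends) - 1)])
        label = np.full(len(t), None, dtype=object)
        year = np.full(len(t), -1)
        labels = self.intervals["label"].to_numpy()
        years = self.intervals["start"].dt.year.to_numpy()
        label[ok] = labels[idx[ok]]
        year[ok] = years[idx[ok]]
        return pd.DataFrame({"label": label, "year": year}, index=t)

    def interval_containing(self, ts) -> pd.Series | None:
        ts = pd.Timestamp(ts)
        if ts.tz is not None:
            ts = ts.tz_localize(None)
        iv = self.intervals
        hit = iv[(iv["start"] <= ts) & (ts < iv["end"])]
        return None if hit.empty else hit.iloc[0]

    def to_csv(self, path) -> None:
        self.intervals[["start", "end", "label"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, thresholds: ThresholdsConfig | None = None):
        iv = pd.read_csv(path, parse_dates=["start", "end"])
        return cls(iv, thresholds or ThresholdsConfig())


def daily_experienced(detections: pd.DataFrame) -> pd.DataFrame:
    """Average-across-fish of per-fish daily minimum sensor temperature.

    Uses the coldest reading per fish per day, then the mean over fish
    with at least one reading that day.
    """
    d = detections.dropna(subset=["temperature"])
    if d.empty:
        raise ValueError("no temperature sensor data in detections")
    ts = pd.DatetimeIndex(d["timestamp"])
    per_fish = (
        d.assign(date=ts.tz_localize(None).normalize() if ts.tz else ts.normalize())
        .groupby(["tag_id", "date"])["temperature"]
        .min()
    )
    series = per_fish.groupby("date").mean()
    return pd.DataFrame({"date": series.index, "experienced": series.to_numpy()})


def smooth(series: pd.Series, window: int = 7) -> pd.Series:
    """Centred rolling mean with shrinking edges; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    return series.rolling(window, center=True, min_periods=1).mean()


def classify_seasons(
    surface: pd.DataFrame,
    thresholds: ThresholdsConfig = ThresholdsConfig(),
    temp_col: str = "surface",
    presmoothed: bool = True,
) -> SeasonCalendar:
    """Run the season state machine over a daily surface series.

    ``surface`` needs columns ``date`` and ``temp_col``.  The series must
    start in a winter-temperature period.  When ``presmoothed`` is False
    the configured rolling average is applied first.
    """
    df = surface.sort_values("date").reset_index(drop=True)
    temps = df[temp_col]
    if not presmoothed:
        temps = smooth(temps, thresholds.rolling_window_days)
    t = temps.to_numpy(dtype=float)
    dates = pd.DatetimeIndex(df["date"])
    if t[0] >= thresholds.spring_onset_c:
        raise ValueError("series must start in a winter-temperature period")

    labels = np.empty(len(t), dtype=object)
    state = "winter"
    saw_summer = False
    for i, temp in enumerate(t):
        if state == "winter" and temp >= thresholds.spring_onset_c:
            state = "spring"
        elif state == "spring":
            if temp > thresholds.summer_onset_c:
                state = "summer"
                saw_summer = True
            elif temp < thresholds.spring_onset_c:
                state = "winter"  # spring collapses back without a summer
        elif state == "summer" and temp < thresholds.fall_onset_c:
            state = "fall"
        elif state == "fall" and temp < thresholds.spring_onset_c:
            state = "winter"
        labels[i] = state
    if not saw_summer:
        warnings.warn("series never exceeded the summer onset: calendar has no summer")

    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, len(t)]
    one_day = pd.Timedelta(days=1)
    iv = pd.DataFrame(
        {
            "start": dates[starts],
            "end": [dates[e - 1] + one_day for e in ends],
            "label": labels[starts],
        }
    )
    return SeasonCalendar(iv, thresholds)


def stratification_breakpoints(
    surface: pd.DataFrame,
    experienced: pd.DataFrame,
    delta_c: float = 1.0,
    min_run_days: int = 5,
) -> tuple[pd.Timestamp | None, pd.Timestamp | None]:
    """Stratification onset and breakdown dates.

    Onset: first date starting >= ``min_run_days`` consecutive days with
    surface - experienced > delta.  Breakdown: first later date starting
    an equally long run with the difference <= delta.  Returns
    (None, None) with a warning when the lake never stratifies.
    """
    m = pd.merge(surface, experienced, on="date", how="inner", suffixes=("", "_e"))
    diff = (m["surface"] - m["experienced"]).to_numpy()
    dates = pd.DatetimeIndex(m["date"])
    above = diff > delta_c

    def first_run(mask, start_at=0):
        run = 0
        for i in range(start_at, len(mask)):
            run = run + 1 if mask[i] else 0
            if run == min_run_days:
                return i - min_run_days + 1
        return None

    i_on = first_run(above)
    if i_on is None:
        warnings.warn("series never stratified; no breakpoints")
        return None, None
    i_off = first_run(~above, start_at=i_on)
    return dates[i_on], (dates[i_off] if i_off is not None else None)
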