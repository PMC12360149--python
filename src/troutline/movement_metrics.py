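"""Centre-of-activity positioning, hex binning, daily movement.

COAs are detection-count-weighted mean receiver positions per clock-
aligned hour bin; movement is summed centroid-to-centroid distance of
the hex cells of consecutive COAs within a season, divided by the
inclusive day span between the first and last COA of that season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["centers_of_activity", "assign_hex", "daily_movement", "MovementSummary"]


def centers_of_activity(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    interval_h: float = 1.0,
) -> pd.DataFrame:
    """COA table: fish, hour, x, y, n (detections in bin).

    Bins are clock-aligned (hour floor); hours without detections emit
    no row.
    """
    rx = receivers.drop_duplicates("receiver_id").set_index("receiver_id")
    det = detections.copy()
    pos = rx.loc[det["receiver_id"], ["x", "y"]].to_numpy(dtype=float)
    det["_x"] = pos[:, 0]
    det["_y"] = pos[:, 1]
    freq = pd.Timedelta(hours=interval_h)
    det["hour"] = pd.DatetimeIndex(det["timestamp"]).floor(freq)
    grouped = det.groupby(["tag_id", "hour"], sort=True)
    coas = grouped.agg(x=("_x", "mean"), y=("_y", "mean"), n=("_x", "size"))
    out = coas.reset_index().rename(columns={"tag_id": "fish"})
    return out[["fish", "hour", "x", "y", "n"]]


def assign_hex(coas: pd.DataFrame, grid) -> pd.DataFrame:
    """Add the containing hex cell id; boundary ties -> lowest id."""
    out = coas.copy()
    if len(out) == 0:
        out["cell"] = []
        return out
    out["cell"] = grid.assign(out[["x", "y"]].to_numpy())
    return out


@dataclass
class MovementSummary:
    fish: str
    season: str
    year: int
    distance_km: float
    days: int
    avg_daily_km: float
    n_coas: int

    def __post_init__(self) -> None:
        if self.distance_km < 0 or self.days < 1:
            raise ValueError("invalid movement summary")


def daily_movement(
    coas: pd.DataFrame,
    calendar,
    grid,
    denominator: str = "span",
) -> pd.DataFrame:
    """Per fish-season movement from hex-assigned COAs.

    ``denominator='span'`` (default) divides by the inclusive day span
    between first and last COA in the season; ``'active'`` divides by
    the count of distinct dates with a COA.  Consecutive COA pairs
    crossing a season boundary contribute to neither season.
    """
    if denominator not in ("span", "active"):
        raise ValueError("denominator must be 'span' or 'active'")
    if "cell" not in coas.columns:
        coas = assign_hex(coas, grid)
    inst = calendar.instance_of_times(coas["hour"])
    df = coas.assign(season=inst["label"].to_numpy(), year=inst["year"].to_numpy())
    df = df[df["season"].notna()]
    rows = []
    for (fish, season, year), grp in df.groupby(["fish", "season", "year"], sort=False):
        grp = grp.sort_values("hour", kind="mergesort")
        cells = grp["cell"].to_numpy()
        if len(grp) >= 2:
            a = np.array([grid.centroid_of(c) for c in cells[:-1]])
            b = np.array([grid.centroid_of(c) for c in cells[1:]])
            dist_km = float(np.hypot(*(b - a).T).sum()) / 1000.0
        else:
            dist_km = 0.0
        dates = pd.DatetimeIndex(grp["hour"]).normalize()
        if denominator == "span":
            days = (dates[-1] - dates[0]).days + 1
        else:
            days = int(dates.nunique())
        days = max(days, 1)
        rows.append(
            MovementSummary(
                fish=fish,
                season=season,
                year=int(year),
                distance_km=dist_km,
                days=days,
                avg_daily_km=dist_km / days,
                n_coas=len(grp),
            )
        )
    return pd.DataFrame(
        [
            {
                "fish": r.fish,
                "season": r.season,
                "year": r.year,
                "distance_km": r.distance_km,
                "days": r.days,
                "avg_daily_km": r.avg_daily_km,
                "n_coas": r.n_coas,
            }
            for r in rows
        ]
    )
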