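"""Correlated random-walk fish tracks constrained to water.

Each fish walks at a fixed per-season speed: every internal step (10 min
by default) has length ``speed * dt`` and a heading drawn as the previous
heading plus wrapped-normal noise, resampled uniformly when the step
would leave the water.  Total realised path length therefore equals
``speed * duration`` exactly, which makes the tracks usable as ground
truth for distance-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import SimConfig
from .lake import LakeGeometry

__all__ = ["TrueTrack", "simulate_fish", "simulate_fish_in_regions", "stationary_track"]

_MAX_RETRIES = 500


@dataclass
class TrueTrack:
    """Ground-truth movement of one simulated fish."""

    fish_id: str
    origin: str  # "stocked" | "wild"
    points: pd.DataFrame  # columns: timestamp, x, y, depth, season
    season_summaries: pd.DataFrame = field(default_factory=pd.DataFrame)
    # season_summaries columns: season, distance_km, mean_depth_m,
    # plus occ_<region> occupancy proportions

    def __post_init__(self) -> None:
        if self.points["depth"].lt(-1e-9).any():
            raise ValueError("negative depth in track")


def _summarise(points: pd.DataFrame, lake: LakeGeometry) -> pd.DataFrame:
    pts = points.copy()
    xy = pts[["x", "y"]].to_numpy()
    pts["region"] = lake.region_of_many(xy)
    step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    pts["step_m"] = np.r_[0.0, step]
    rows = []
    for season, grp in pts.groupby("season", sort=False):
        row = {
            "season": season,
            "distance_km": grp["step_m"].iloc[1:].sum() / 1000.0,
            "mean_depth_m": grp["depth"].mean(),
        }
        occ = grp["region"].value_counts(normalize=True)
        for label in lake.region_labels:
            row[f"occ_{label}"] = float(occ.get(label, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def _walk(
    rng: np.random.Generator,
    lake: LakeGeometry,
    start_xy: np.ndarray,
    times: pd.DatetimeIndex,
    step_len: np.ndarray,
    turn_sd: float,
    inside=None,
) -> np.ndarray:
    """Run one constrained walk; returns (n, 2) positions."""
    if inside is None:
        inside = lake.contains
    pos = np.empty((len(times), 2))
    pos[0] = start_xy
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(1, len(times)):
        ln = step_len[i - 1]
        if ln == 0.0:
            pos[i] = pos[i - 1]
            continue
        cand_heading = heading + rng.normal(0.0, turn_sd) if turn_sd > 0 else heading
        for attempt in range(_MAX_RETRIES):
            nx = pos[i - 1, 0] + ln * np.cos(cand_heading)
            ny = pos[i - 1, 1] + ln * np.sin(cand_heading)
            if inside(nx, ny):
                break
            cand_heading = rng.uniform(0, 2 * np.pi)
        else:
            raise RuntimeError(
                "could not place step inside water after "
                f"{_MAX_RETRIES} retries (speed too high for lake?)"
            )
        heading = cand_heading
        pos[i] = (nx, ny)
    return pos


def _season_of_times(times: pd.DatetimeIndex, calendar) -> np.ndarray:
    return calendar.label_times(times)


def simulate_fish(
    lake: LakeGeometry,
    calendar,
    config: SimConfig,
    start_positions: dict | None = None,
) -> list[TrueTrack]:
    """Simulate ``config.n_fish_per_origin`` fish per origin.

    Per-fish RNG sub-streams are spawned from the global seed so results
    are reproducible regardless of iteration order.
    """
    start = pd.Timestamp(config.study_start, tz="UTC")
    end = pd.Timestamp(config.study_end, tz="UTC")
    times = pd.date_range(start, end, freq=f"{int(config.step_minutes)}min")
    if len(times) < 2:
        raise ValueError("study window shorter than one step")
    seasons = _season_of_times(times, calendar)
    dt_days = config.step_minutes / (60.0 * 24.0)
    tracks = []
    fish_idx = 0
    for origin in ("stocked", "wild"):
        for j in range(config.n_fish_per_origin):
            rng = np.random.default_rng([config.seed, fish_idx])
            fish_id = f"{origin[0].upper()}{j:03d}"
            if start_positions and fish_id in start_positions:
                start_xy = np.asarray(start_positions[fish_id], float)
            else:
                start_xy = _random_water_point(rng, lake)
            speed = np.array(
                [
                    config.behaviour_for(origin, s).speed_km_day * 1000.0 * dt_days
                    for s in seasons[:-1]
                ]
            )
            pos = _walk(rng, lake, start_xy, times, speed, config.turn_sd_rad)
            depth = _seasonal_depths(rng, lake, config, origin, seasons, pos)
            pts = pd.DataFrame(
                {
                    "timestamp": times,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "depth": depth,
                    "season": seasons,
                }
            )
            track = TrueTrack(fish_id, origin, pts)
            track.season_summaries = _summarise(pts, lake)
            tracks.append(track)
            fish_idx += 1
    return tracks


def _random_water_point(rng: np.random.Generator, lake: LakeGeometry) -> np.ndarray:
    minx, miny, maxx, maxy = lake.water.bounds
    for _ in range(_MAX_RETRIES):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if lake.contains(x, y):
            return np.array([x, y])
    raise RuntimeError("could not sample a water start point")


def _seasonal_depths(rng, lake, config, origin, seasons, pos) -> np.ndarray:
    depth = np.empty(len(pos))
    local = np.array([lake.depth_at(x, y) for x, y in pos])
    for s in pd.unique(seasons):
        mask = seasons == s
        beh = config.behaviour_for(origin, s)
        draw = rng.normal(beh.depth_mean_m, beh.depth_sd_m, mask.sum())
        depth[mask] = draw
    return np.clip(depth, 0.0, local)


def simulate_fish_in_regions(
    lake: LakeGeometry,
    schedule: list,
    config: SimConfig,
    fish_id: str = "F000",
    origin: str = "stocked",
    speed_km_day: float = 3.0,
    depth_mean_m: float = 25.0,
    depth_sd_m: float = 5.0,
    rng: np.random.Generator | None = None,
) -> TrueTrack:
    """Walk confined to scheduled regions: ``schedule`` is a list of
    ``(start, end, region_label)`` with contiguous half-open intervals.

    Gives exact control over true regional occupancy, which free walks
    do not.
    """
    import shapely

    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    dt_days = config.step_minutes / (60.0 * 24.0)
    step_m = speed_km_day * 1000.0 * dt_days
    prev_end_pos = None
    for seg_start, seg_end, label in schedule:
        poly = lake.regions[label]
        times = pd.date_range(
            pd.Timestamp(seg_start, tz="UTC"),
            pd.Timestamp(seg_end, tz="UTC"),
            freq=f"{int(config.step_minutes)}min",
            inclusive="left",
        )
        if len(times) == 0:
            continue

        def inside(x, y, _poly=poly):
            return bool(shapely.contains_xy(_poly, x, y))

        if prev_end_pos is not None and inside(*prev_end_pos):
            start_xy = prev_end_pos
        else:
            minx, miny, maxx, maxy = poly.bounds
            while True:
                cand = rng.uniform([minx, miny], [maxx, maxy])
                if inside(*cand):
                    start_xy = cand
                    break
        lens = np.full(len(times) - 1, step_m) if len(times) > 1 else np.array([])
        pos = _walk(rng, lake, start_xy, times, lens, config.turn_sd_rad, inside=inside)
        prev_end_pos = pos[-1]
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": times,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "depth": np.clip(
                        rng.normal(depth_mean_m, depth_sd_m, len(times)),
                        0.0,
                        None,
                    ),
                    "season": "all",
                }
            )
        )
    pts = pd.concat(frames, ignore_index=True)
    track = TrueTrack(fish_id, origin, pts)
    track.season_summaries = _summarise(pts, lake)
    return track


def stationary_track(
    fish_id: str,
    origin: str,
    position,
    depth: float,
    start,
    end,
    step_minutes: float = 10.0,
) -> TrueTrack:
    """A fish that never moves — handy for planting dead fish."""
    times = pd.date_range(
        pd.Timestamp(start, tz="UTC"),
        pd.Timestamp(end, tz="UTC"),
        freq=f"{int(step_minutes)}min",
    )
    pts = pd.DataFrame(
        {
            "timestamp": times,
            "x": float(position[0]),
            "y": float(position[1]),
            "depth": float(depth),
            "season": "all",
        }
    )
    return TrueTrack(fish_id, origin, pts)
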