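"""Depth-day eligibility, fixed-size subsampling and daily summaries.

A (fish, date, region) day is eligible only with more than 20 depth-
bearing detections in that region; each eligible day is summarised from
exactly 20 uniformly subsampled values, with the subsample seed recorded
so the draw is reproducible and never redrawn per analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "eligible_depth_days",
    "subsample_depths",
    "station_depth_covariate",
    "daily_depth_table",
]


def _with_date_region(detections: pd.DataFrame, receivers: pd.DataFrame) -> pd.DataFrame:
    rx = receivers.drop_duplicates("receiver_id").set_index("receiver_id")
    det = detections.copy()
    det["region"] = rx["region"].reindex(det["receiver_id"]).to_numpy()
    det["station_depth"] = rx["depth"].reindex(det["receiver_id"]).to_numpy()
    ts = pd.DatetimeIndex(det["timestamp"])
    if ts.tz is not None:
        ts = ts.tz_localize(None)
    det["date"] = ts.normalize()
    return det


def eligible_depth_days(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    min_detections: int = 20,
) -> pd.DataFrame:
    """(tag_id, date, region) combinations with more than
    ``min_detections`` depth-bearing detections."""
    det = _with_date_region(detections, receivers).dropna(subset=["depth"])
    counts = (
        det.groupby(["tag_id", "date", "region"]).size().rename("n_depth").reset_index()
    )
    return counts[counts["n_depth"] > min_detections].reset_index(drop=True)


def subsample_depths(
    day_detections: pd.DataFrame,
    size: int = 20,
    seed: int = 0,
    min_detections: int = 20,
    station_weighting: str = "detection",
) -> dict:
    """Summarise one eligible fish-day-region from a fixed-size subsample.

    Draws ``size`` depth values uniformly without replacement, returns
    the subsample mean, sample standard deviation (ddof=1), the
    station-depth covariate and the seed used.
    """
    d = day_detections.dropna(subset=["depth"])
    if len(d) <= min_detections:
        raise ValueError(
            f"day has {len(d)} depth detections; eligibility requires > {min_detections}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(d), size=size, replace=False)
    sub = d.iloc[np.sort(idx)]
    return {
        "mean_depth": float(sub["depth"].mean()),
        "sd_depth": float(sub["depth"].std(ddof=1)),
        "station_depth": station_depth_covariate(sub, weighting=station_weighting),
        "seed": seed,
        "n_available": len(d),
    }


def station_depth_covariate(subsample: pd.DataFrame, weighting: str = "detection") -> float:
    """Average station depth of the subsampled detections.

    ``'detection'`` (default) weights each detection by itself (the 20
    values carry their station's depth); ``'station'`` averages distinct
    station depths once each.
    """
    if subsample["station_depth"].isna().any():
        raise ValueError("missing station depth for a contributing receiver")
    if weighting == "detection":
        return float(subsample["station_depth"].mean())
    if weighting == "station":
        return float(subsample["station_depth"].drop_duplicates().mean())
    raise ValueError("weighting must be 'detection' or 'station'")


def daily_depth_table(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    seed: int = 0,
    size: int = 20,
    min_detections: int = 20,
    station_weighting: str = "detection",
) -> pd.DataFrame:
    """DepthDaily table over all eligible fish-day-regions.

    One subsample per fish-day drawn once with a recorded per-day seed
    derived from the global seed.
    """
    det = _with_date_region(detections, receivers).dropna(subset=["depth"])
    rows = []
    for i, ((tag, date, region), grp) in enumerate(
        det.groupby(["tag_id", "date", "region"], sort=True)
    ):
        if len(grp) <= min_detections:
            continue
        day_seed = int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1))
        summ = subsample_depths(
            grp,
            size=size,
            seed=day_seed,
            min_detections=min_detections,
            station_weighting=station_weighting,
        )
        rows.append(
            {
                "fish": tag,
                "date": date,
                "region": region,
                "mean_depth": summ["mean_depth"],
                "sd_depth": summ["sd_depth"],
                "station_depth": summ["station_depth"],
                "seed": summ["seed"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fish",
            "date",
            "region",
            "mean_depth",
            "sd_depth",
            "station_depth",
            "seed",
        ],
    )
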