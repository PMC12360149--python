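"""Synthetic daily near-surface and fish-experienced temperature series.

The surface series is a smooth annual cosine; the experienced series
equals the surface series whenever the lake is unstratified (surface
below the stratification threshold) and is capped at the hypolimnion
temperature while stratified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TemperatureConfig", "simulate_temperature", "attach_temperature"]


@dataclass(frozen=True)
class TemperatureConfig:
    min_c: float = 2.0
    max_c: float = 24.0
    coldest_doy: int = 35  # day of year of the annual minimum
    stratification_threshold_c: float = 8.0
    hypolimnion_c: float = 9.0
    period_days: float = 365.0


def simulate_temperature(
    start, end, config: TemperatureConfig = TemperatureConfig()
) -> pd.DataFrame:
    """Daily surface and experienced series over [start, end].

    Returns a frame with columns date, surface, experienced.
    """
    dates = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    mid = (config.max_c + config.min_c) / 2.0
    amp = (config.max_c - config.min_c) / 2.0
    surface = mid - amp * np.cos(
        2 * np.pi * (doy - config.coldest_doy) / config.period_days
    )
    stratified = surface >= config.stratification_threshold_c
    experienced = np.where(
        stratified, np.minimum(surface, config.hypolimnion_c), surface
    )
    return pd.DataFrame({"date": dates, "surface": surface, "experienced": experienced})


def attach_temperature(
    track,
    temps: pd.DataFrame,
    thermocline_depth_m: float = 15.0,
    config: TemperatureConfig = TemperatureConfig(),
):
    """Add a ``temperature`` column to a track's points.

    A fish below the thermocline during stratification experiences the
    hypolimnion temperature; otherwise it experiences the surface value
    for that date.
    """
    pts = track.points
    daily = temps.set_index(pd.DatetimeIndex(temps["date"]).date)
    dates = pts["timestamp"].dt.date
    surface = daily["surface"].reindex(dates).to_numpy()
    stratified = surface >= config.stratification_threshold_c
    deep = pts["depth"].to_numpy() >= thermocline_depth_m
    temp = np.where(
        stratified & deep, np.minimum(surface, config.hypolimnion_c), surface
    )
    track.points = pts.assign(temperature=temp)
    return track
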