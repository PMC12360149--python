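"""Acoustic detection simulator.

Transmission times are cumulative sums of independent uniform delays;
each transmission is detected independently by every in-range, active
receiver with probability from a two-parameter logistic range curve
fitted exactly through the configured calibration points.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..config import SimConfig

__all__ = [
    "fit_detection_curve",
    "detection_probability",
    "simulate_detections",
]


def fit_detection_curve(calibration) -> tuple[float, float]:
    """Return (r50, scale) of p(r) = 1 / (1 + exp((r - r50) / scale)).

    With exactly two calibration points the curve passes through both;
    with more, a least-squares fit on the logit scale is used. The
    calibration must be strictly decreasing in probability with range.
    """
    cal = sorted((float(r), float(p)) for r, p in calibration)
    if len(cal) < 2:
        raise ValueError("need at least two calibration points")
    ranges = np.array([r for r, _ in cal])
    probs = np.array([p for _, p in cal])
    if not np.all(np.diff(probs) < 0):
        raise ValueError("calibration must be strictly decreasing in range")
    logits = np.log(probs / (1.0 - probs))
    # logit(p) = (r50 - r)/scale  ->  linear in r
    slope, intercept = np.polyfit(ranges, logits, 1)
    scale = -1.0 / slope
    r50 = intercept * scale
    if scale <= 0:
        raise ValueError("fitted curve is not decreasing")
    return r50, scale


def detection_probability(r, curve: tuple[float, float]) -> np.ndarray:
    r50, scale = curve
    return 1.0 / (1.0 + np.exp((np.asarray(r, dtype=float) - r50) / scale))


def transmission_times(
    rng: np.random.Generator, start: pd.Timestamp, end: pd.Timestamp, bounds
) -> pd.DatetimeIndex:
    """Cumulative sums of uniform(lo, hi) second delays inside [start, end]."""
    lo, hi = bounds
    total_s = (end - start).total_seconds()
    n_est = int(total_s / lo) + 10
    delays = rng.uniform(lo, hi, n_est)
    t = np.cumsum(delays)
    t = t[t <= total_s]
    while t.size and total_s - t[-1] > hi:  # pragma: no cover - generous n_est
        extra = rng.uniform(lo, hi, 100)
        t = np.r_[t, t[-1] + np.cumsum(extra)]
        t = t[t <= total_s]
    return start + pd.to_timedelta(t, unit="s")


def simulate_detections(
    tracks,
    receivers: pd.DataFrame,
    config: SimConfig,
    max_range_m: float | None = None,
) -> pd.DataFrame:
    """Simulate a detection table for ``tracks`` against ``receivers``.

    ``receivers`` columns: receiver_id, station_id, x, y, depth,
    deploy_start, deploy_end, region.  Sensor-tagged fish (those whose
    track carries a ``temperature`` column, or all fish if absent ->
    depth only) emit depth/temperature sensor values.

    Returns detections sorted by timestamp with columns
    tag_id, receiver_id, timestamp, depth, temperature.
    """
    if len(receivers) == 0:
        raise ValueError("receivers table is empty")
    curve = fit_detection_curve(config.range_calibration)
    if max_range_m is None:
        # beyond this the detection probability is < 1e-4
        max_range_m = curve[0] + curve[1] * np.log(1e4)
    rx = receivers.copy()
    rx["deploy_start"] = pd.to_datetime(rx["deploy_start"], utc=True)
    rx["deploy_end"] = pd.to_datetime(rx["deploy_end"], utc=True)

    frames = []
    for k, track in enumerate(tracks):
        rng = np.random.default_rng([config.seed, 7919, k])
        pts = track.points
        t0, t1 = pts["timestamp"].iloc[0], pts["timestamp"].iloc[-1]
        tx = transmission_times(rng, t0, t1, config.delay_bounds_s)
        if len(tx) == 0:
            continue
        tsec = (pts["timestamp"] - t0).dt.total_seconds().to_numpy()
        txsec = (tx - t0).total_seconds().to_numpy()
        fx = np.interp(txsec, tsec, pts["x"].to_numpy())
        fy = np.interp(txsec, tsec, pts["y"].to_numpy())
        fdepth = np.interp(txsec, tsec, pts["depth"].to_numpy())
        has_temp = "temperature" in pts.columns
        ftemp = (
            np.interp(txsec, tsec, pts["temperature"].to_numpy())
            if has_temp
            else np.full(len(tx), np.nan)
        )
        sensor = getattr(track, "sensor", True)
        for _, r in rx.iterrows():
            dist = np.hypot(fx - r["x"], fy - r["y"])
            near = dist <= max_range_m
            if not near.any():
                continue
            active = (tx >= r["deploy_start"]) & (tx < r["deploy_end"])
            cand = near & np.asarray(active)
            if not cand.any():
                continue
            p = detection_probability(dist[cand], curve)
            hit = rng.random(cand.sum()) < p
            if not hit.any():
                continue
            idx = np.flatnonzero(cand)[hit]
            frames.append(
                pd.DataFrame(
                    {
                        "tag_id": track.fish_id,
                        "receiver_id": r["receiver_id"],
                        "timestamp": tx[idx],
                        "depth": fdepth[idx] if sensor else np.nan,
                        "temperature": ftemp[idx] if sensor else np.nan,
                    }
                )
            )
    if not frames:
        warnings.warn("no receiver active during window: empty detection table")
        return pd.DataFrame(
            columns=["tag_id", "receiver_id", "timestamp", "depth", "temperature"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def receiver_grid(
    lake,
    spacing_m: float,
    deploy_start,
    deploy_end,
    depth_fraction: float = 0.8,
) -> pd.DataFrame:
    """Dense rectangular receiver array over the water body (test rig)."""
    minx, miny, maxx, maxy = lake.water.bounds
    xs = np.arange(minx + spacing_m / 2, maxx, spacing_m)
    ys = np.arange(miny + spacing_m / 2, maxy, spacing_m)
    rows = []
    i = 0
    for x in xs:
        for y in ys:
            region = lake.region_of(x, y)
            if region is None:
                continue
            rows.append(
                {
                    "receiver_id": f"R{i:04d}",
                    "station_id": f"S{i:04d}",
                    "x": x,
                    "y": y,
                    "depth": lake.region_depth[region] * depth_fraction,
                    "deploy_start": pd.Timestamp(deploy_start, tz="UTC"),
                    "deploy_end": pd.Timestamp(deploy_end, tz="UTC"),
                    "region": region,
                }
            )
            i += 1
    return pd.DataFrame(rows)
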