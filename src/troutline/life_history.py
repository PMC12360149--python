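"""Length projection and maturity assignment.

Growth follows a von Bertalanffy daily-increment scheme anchored at the
length at capture: dL/day = k * (Linf - L) / 365.25.  Fish captured at
or above Linf keep their capture length for the whole record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthModel",
    "maturity_cutoff_from_bins",
    "project_length",
    "maturity_status",
]


@dataclass(frozen=True)
class GrowthModel:
    """Origin-specific von Bertalanffy parameters."""

    l_inf_mm: float
    k_per_year: float

    def __post_init__(self) -> None:
        if self.l_inf_mm <= 0 or self.k_per_year <= 0:
            raise ValueError("Linf and k must be positive")


#: documented defaults (per-origin growth is config, not printed data)
DEFAULT_GROWTH = {
    "stocked": GrowthModel(l_inf_mm=850.0, k_per_year=0.25),
    "wild": GrowthModel(l_inf_mm=850.0, k_per_year=0.30),
}


def maturity_cutoff_from_bins(bins: pd.DataFrame, bin_width: float = 25.0) -> float:
    """Lower edge of the smallest bin where every group exceeds 50% mature.

    ``bins`` columns: bin_low, group, prop_mature; bins contiguous and
    ``bin_width`` wide for each group.
    """
    if not bins["prop_mature"].between(0, 1).all():
        raise ValueError("prop_mature must lie in [0, 1]")
    pivot = bins.pivot_table(index="bin_low", columns="group", values="prop_mature")
    edges = pivot.index.to_numpy(dtype=float)
    if len(edges) > 1 and not np.allclose(np.diff(edges), bin_width):
        raise ValueError(f"bins must be contiguous with width {bin_width}")
    all_over = (pivot > 0.5).all(axis=1)
    if not all_over.any():
        firsts = {
            g: (pivot[g][pivot[g] > 0.5].index.min() if (pivot[g] > 0.5).any() else None)
            for g in pivot.columns
        }
        raise ValueError(f"no bin qualifies for all groups; per-group firsts: {firsts}")
    return float(all_over.idxmax())


def project_length(fish: pd.Series | dict, date, model: GrowthModel) -> float:
    """Projected length (mm) of a fish on ``date``.

    Equals the closed form of the daily Euler scheme,
    L(n) = Linf - (Linf - L0) * (1 - k/365.25)**n, with n whole days
    since capture; constant when the capture length is at or above Linf.
    """
    cap_date = pd.Timestamp(fish["capture_date"])
    date = pd.Timestamp(date)
    if cap_date.tz is not None:
        cap_date = cap_date.tz_localize(None)
    if date.tz is not None:
        date = date.tz_localize(None)
    n_days = (date.normalize() - cap_date.normalize()).days
    if n_days < 0:
        raise ValueError("projection date precedes capture date")
    l0 = float(fish["capture_length"])
    if l0 >= model.l_inf_mm:
        return l0
    decay = (1.0 - model.k_per_year / 365.25) ** n_days
    return model.l_inf_mm - (model.l_inf_mm - l0) * decay


def project_length_series(fish, dates, model: GrowthModel) -> np.ndarray:
    """Vectorised :func:`project_length` over many dates."""
    cap_date = pd.Timestamp(fish["capture_date"])
    if cap_date.tz is not None:
        cap_date = cap_date.tz_localize(None)
    d = pd.DatetimeIndex(dates)
    if d.tz is not None:
        d = d.tz_localize(None)
    n_days = (d.normalize() - cap_date.normalize()).days.to_numpy()
    if (n_days < 0).any():
        raise ValueError("projection date precedes capture date")
    l0 = float(fish["capture_length"])
    if l0 >= model.l_inf_mm:
        return np.full(len(d), l0)
    decay = (1.0 - model.k_per_year / 365.25) ** n_days
    return model.l_inf_mm - (model.l_inf_mm - l0) * decay


def maturity_status(length_mm: float, cutoff_mm: float = 500.0) -> str:
    """'immature' iff length <= cutoff, else 'mature'."""
    if length_mm <= 0:
        raise ValueError("length must be positive")
    return "immature" if length_mm <= cutoff_mm else "mature"


def season_midpoint_status(
    fish, calendar, model: GrowthModel, cutoff_mm: float = 500.0
) -> pd.DataFrame:
    """Maturity status at each season-instance midpoint after capture."""
    iv = calendar.intervals
    rows = []
    for _, r in iv.iterrows():
        mid = r["start"] + (r["end"] - r["start"]) / 2
        cap = pd.Timestamp(fish["capture_date"])
        if cap.tz is not None:
            cap = cap.tz_localize(None)
        if mid < cap:
            continue
        length = project_length(fish, mid, model)
        rows.append(
            {
                "label": r["label"],
                "year": r["start"].year,
                "length_mm": length,
                "status": maturity_status(length, cutoff_mm),
            }
        )
    return pd.DataFrame(rows)
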