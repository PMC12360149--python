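"""Shared configuration objects.

All fixed analysis constants live in :class:`ThresholdsConfig`; simulator
settings live in :class:`SimConfig`.  Both are plain dataclasses that
validate on construction and can round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


@dataclass(frozen=True)
class ThresholdsConfig:
    """Fixed constants used across the analysis pipeline.

    Temperature thresholds (degC) drive the biological-season state
    machine; the remaining fields parameterise filtering, positioning
    and model selection.
    """

    spring_onset_c: float = 8.0
    summer_onset_c: float = 17.0
    fall_onset_c: float = 15.0
    rolling_window_days: int = 7
    maturity_cutoff_mm: float = 500.0
    depth_day_min_detections: int = 20
    depth_subsample_size: int = 20
    coa_interval_h: float = 1.0
    hex_spacing_km: float = 1.0
    aic_window: float = 2.0
    alpha: float = 0.05
    dead_residency_days: float = 30.0
    dead_depth_sd_m: float = 1.0
    spurious_window_h: float = 1.0
    water_graph_resolution_m: float = 250.0

    def __post_init__(self) -> None:
        for name in (
            "spring_onset_c",
            "summer_onset_c",
            "fall_onset_c",
            "rolling_window_days",
            "maturity_cutoff_mm",
            "depth_day_min_detections",
            "depth_subsample_size",
            "coa_interval_h",
            "hex_spacing_km",
            "aic_window",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.summer_onset_c > self.spring_onset_c:
            raise ValueError("summer onset must exceed spring onset")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdsConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


#: detection-range calibration defaults: (range m, detection probability)
DEFAULT_RANGE_CALIBRATION: tuple[tuple[float, float], ...] = (
    (250.0, 0.70),
    (500.0, 0.30),
)


@dataclass
class SeasonBehaviour:
    """Per-season movement/depth behaviour for one origin."""

    speed_km_day: float = 3.0
    depth_mean_m: float = 25.0
    depth_sd_m: float = 8.0

    def __post_init__(self) -> None:
        if self.speed_km_day < 0:
            raise ValueError("speed must be >= 0")
        if self.depth_sd_m < 0:
            raise ValueError("depth sd must be >= 0")


@dataclass
class SimConfig:
    """Settings for the synthetic lake / fish / detection generator."""

    seed: int = 0
    n_fish_per_origin: int = 10
    # origin -> season label -> behaviour
    behaviour: dict = field(default_factory=dict)
    delay_bounds_s: tuple[float, float] = (80.0, 160.0)
    range_calibration: Sequence[tuple[float, float]] = DEFAULT_RANGE_CALIBRATION
    study_start: str = "2021-01-01"
    study_end: str = "2021-12-31"
    # lake layout: list of (label, width_m, height_m, depth_m) chained west->east
    regions: Sequence[tuple[str, float, float, float]] = (
        ("A", 10_000.0, 40_000.0, 60.0),
    )
    islands: Sequence[tuple[float, float, float]] = ()  # (cx, cy, radius_m)
    hex_spacing_m: float = 1000.0
    step_minutes: float = 10.0
    turn_sd_rad: float = 0.6

    def __post_init__(self) -> None:
        lo, hi = self.delay_bounds_s
        if not (0 < lo < hi):
            raise ValueError("delay bounds must satisfy 0 < lo < hi")
        for r, p in self.range_calibration:
            if not (0.0 < p < 1.0):
                raise ValueError("calibration probabilities must lie in (0,1)")
            if r <= 0:
                raise ValueError("calibration ranges must be positive")
        for origin_map in self.behaviour.values():
            for beh in origin_map.values():
                if not isinstance(beh, SeasonBehaviour):
                    raise TypeError("behaviour values must be SeasonBehaviour")

    def behaviour_for(self, origin: str, season: str) -> SeasonBehaviour:
        return self.behaviour.get(origin, {}).get(season, SeasonBehaviour())
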