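import numpy as np
import pandas as pd
import pytest

from troutline.config import SeasonBehaviour, SimConfig, ThresholdsConfig
from troutline.seasons import SeasonCalendar, classify_seasons, smooth
from troutline.synthetic import make_lake, simulate_temperature


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdsConfig()


@pytest.fixture(scope="session")
def small_lake():
    """Single rectangular region, 10 x 40 km."""
    cfg = SimConfig(regions=(("A", 10_000.0, 40_000.0, 60.0),))
    return make_lake(cfg)


@pytest.fixture(scope="session")
def two_region_lake():
    cfg = SimConfig(
        regions=(("A", 12_000.0, 8_000.0, 60.0), ("B", 12_000.0, 8_000.0, 40.0)),
    )
    return make_lake(cfg)


@pytest.fixture(scope="session")
def island_lake():
    cfg = SimConfig(
        regions=(("A", 8_000.0, 6_000.0, 50.0),),
        islands=((4_000.0, 0.0, 1_500.0),),
    )
    return make_lake(cfg)


@pytest.fixture(scope="session")
def annual_calendar():
    temps = simulate_temperature("2020-12-01", "2022-01-31")
    temps["surface"] = smooth(temps["surface"], 7)
    return classify_seasons(temps)


@pytest.fixture
def simple_calendar(thresholds):
    """Four fixed quarters of 2021 for hand-computed examples."""
    iv = pd.DataFrame(
        {
            "start": pd.to_datetime(
                ["2021-01-01", "2021-04-01", "2021-07-01", "2021-10-01"]
            ),
            "end": pd.to_datetime(
                ["2021-04-01", "2021-07-01", "2021-10-01", "2022-01-01"]
            ),
            "label": ["winter", "spring", "summer", "fall"],
        }
    )
    return SeasonCalendar(iv, thresholds)


def make_detections(rows):
    """rows: (tag, receiver, iso_ts[, depth[, temp]]) tuples."""
    recs = []
    for r in rows:
        tag, rx, ts = r[0], r[1], r[2]
        depth = r[3] if len(r) > 3 else np.nan
        temp = r[4] if len(r) > 4 else np.nan
        recs.append(
            {
                "tag_id": tag,
                "receiver_id": rx,
                "timestamp": pd.Timestamp(ts, tz="UTC"),
                "depth": depth,
                "temperature": temp,
            }
        )
    return (
        pd.DataFrame(recs)
        .sort_values(["tag_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )


@pytest.fixture
def det_factory():
    return make_detections
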