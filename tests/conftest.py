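import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from camshield.records import DEFAULT_GUILD_MAP

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_records(rows):
    """Build a record table from (station, species, timestamp[, camera]) tuples."""
    df = pd.DataFrame(rows, columns=["station_id", "species", "timestamp", "camera_id"][: len(rows[0])] if rows else ["station_id", "species", "timestamp"])
    if "camera_id" not in df.columns:
        df["camera_id"] = pd.NA
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_design(stations, start="2016-01-01", n_occasions=20, grids=None):
    grids = list(stations) if grids is None else grids
    return pd.DataFrame(
        {
            "station_id": list(stations),
            "grid_label": grids,
            "start_date": pd.Timestamp(start),
            "n_occasions": n_occasions,
        }
    )


@pytest.fixture
def guild_map():
    return DEFAULT_GUILD_MAP


@pytest.fixture
def small_survey():
    """Three-station survey with detections of all three guilds."""
    design = make_design(["A", "B", "C"], n_occasions=5)
    records = make_records(
        [
            ("A", "spotted deer", "2016-01-01 08:00:00"),
            ("A", "tiger", "2016-01-02 23:15:00"),
            ("A", "human", "2016-01-03 10:30:00"),
            ("B", "human", "2016-01-01 12:00:00"),
            ("B", "sambar deer", "2016-01-04 02:00:00"),
            ("C", "wild boar", "2016-01-05 14:37:00"),
        ]
    )
    return records, design
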