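"""Camera-trap detection records: reading, validation, independence
filtering and detection-history construction.

Records are held as a :class:`pandas.DataFrame` with columns
``station_id``, ``species``, ``timestamp`` (datetime64, second precision)
and optionally ``camera_id``.  A survey design table gives, per station,
the grid cell it samples, the deployment start date and the number of
daily occasions.  Detection histories are site x occasion binary matrices
built at the guild level (prey / predator / human).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"
RECORD_COLUMNS = ("station_id", "species", "timestamp")
DESIGN_COLUMNS = ("station_id", "grid_label", "start_date", "n_occasions")

#: Default species -> guild assignment: four ungulate prey species, two
#: large felid predators, and humans as their own detection unit.
DEFAULT_SPECIES_GUILDS: dict[str, str] = {
    "sambar deer": "prey",
    "spotted deer": "prey",
    "wild boar": "prey",
    "barking deer": "prey",
    "tiger": "predator",
    "leopard": "predator",
    "human": "human",
}


@dataclass(frozen=True)
class GuildMap:
    """Total mapping from species name to guild name.

    A species belongs to exactly one guild (the mapping is a dict, so
    double membership cannot be expressed).  Guild order follows first
    appearance in the mapping and is the canonical guild order used by
    every downstream analysis.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("guild map must not be empty")

    @property
    def guilds(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return tuple(seen)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def guild_of(self, species: str) -> str:
        try:
            return self.mapping[species]
        except KeyError:
            raise KeyError(f"species {species!r} is not in the guild map") from None

    def members(self, guild: str) -> tuple[str, ...]:
        out = tuple(s for s, g in self.mapping.items() if g == guild)
        if not out:
            raise KeyError(f"unknown guild {guild!r}")
        return out

    def __contains__(self, species: object) -> bool:
        return species in self.mapping


DEFAULT_GUILD_MAP = GuildMap(DEFAULT_SPECIES_GUILDS)


@dataclass
class DetectionHistory:
    """Per-guild site x occasion detection matrix.

    ``matrix`` is float-valued with entries 0.0 (station active, guild not
    detected), 1.0 (detected) or NaN (occasion outside the station's
    deployment window).
    """

    guild: str
    stations: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("detection history matrix must be 2-D")
        if len(self.stations) != self.matrix.shape[0]:
            raise ValueError("station labels do not match matrix rows")
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("detection history entries must be 0, 1 or missing")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    def detections_per_site(self) -> np.ndarray:
        return np.nansum(self.matrix, axis=1)

    def occasions_per_site(self) -> np.ndarray:
        return (~np.isnan(self.matrix)).sum(axis=1)


def read_records(path, sep: str = ",", guild_map: GuildMap | None = None) -> pd.DataFrame:
    """Read a delimited camera-trap record file.

    The header must name ``station_id``, ``species`` and ``timestamp``
    (``camera_id`` optional).  Timestamps must parse as
    ``YYYY-MM-DD HH:MM:SS``; an unparseable timestamp raises a
    ``ValueError`` naming the offending data row.  Species missing from
    ``guild_map`` (default: the standard prey/predator/human map) trigger a
    warning but are retained; they are excluded later when histories are
    built.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file is missing required columns: {missing}")
    if "camera_id" not in df.columns:
        df["camera_id"] = pd.NA
    df = df[["station_id", "species", "timestamp", "camera_id"]].copy()
    ts = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT, errors="coerce")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {df['timestamp'].iloc[row]!r} in data row "
            f"{row + 1} (expected {TIMESTAMP_FORMAT.replace('%', '')})"
        )
    df["timestamp"] = ts
    gm = DEFAULT_GUILD_MAP if guild_map is None else guild_map
    unknown = sorted(set(df["species"].dropna()) - set(gm.species))
    if unknown:
        warnings.warn(
            f"records contain species outside the guild map: {unknown}; "
            "they are retained but ignored by guild-level analyses",
            stacklevel=2,
        )
    return df


def read_design(path, sep: str = ",") -> pd.DataFrame:
    """Read a survey-design table (station, grid, start date, occasions)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design file is missing required columns: {missing}")
    df = df[list(DESIGN_COLUMNS)].copy()
    df["start_date"] = pd.to_datetime(df["start_date"], format="%Y-%m-%d")
    df["n_occasions"] = df["n_occasions"].astype(int)
    return validate_design(df)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    if design["station_id"].duplicated().any():
        dupes = design.loc[design["station_id"].duplicated(), "station_id"].tolist()
        raise ValueError(f"duplicate station ids in design: {dupes}")
    if (design["n_occasions"] < 1).any():
        raise ValueError("n_occasions must be >= 1 for every station")
    return design


def filter_independent(
    records: pd.DataFrame,
    window_minutes: float = 15.0,
    scope: str = "station",
) -> pd.DataFrame:
    """Greedy independence filter on detection records.

    Within each group — ``(station, species)`` by default, or ``species``
    alone when ``scope='survey'`` — events are scanned in time order; the
    first is retained, and each later event is retained iff it falls at
    least ``window_minutes`` after the **last retained** event of the
    group.  The scan is anchored at retained events, which makes the
    filter deterministic and idempotent.  Output is sorted by timestamp
    (then station, species).
    """
    if window_minutes < 0:
        raise ValueError("independence window must be non-negative")
    if scope not in ("station", "survey"):
        raise ValueError(f"unknown filter scope {scope!r}")
    keys = ["station_id", "species"] if scope == "station" else ["species"]
    window = pd.Timedelta(minutes=window_minutes)
    keep: list[int] = []
    ordered = records.sort_values(keys + ["timestamp"], kind="mergesort")
    for _, grp in ordered.groupby(keys, sort=False):
        last_kept = None
        for idx, t in zip(grp.index, grp["timestamp"]):
            if last_kept is None or t - last_kept >= window:
                keep.append(idx)
                last_kept = t
    out = records.loc[keep]
    return out.sort_values(
        ["timestamp", "station_id", "species"], kind="mergesort"
    ).reset_index(drop=True)


def build_detection_history(
    records: pd.DataFrame,
    design: pd.DataFrame,
    guild_map: GuildMap,
    guild: str,
) -> DetectionHistory:
    """Collapse records to a guild-level daily detection history.

    Entry (site, day) is 1 if any member species of the guild was recorded
    at that station on that calendar day inside the deployment window, 0
    if the station was active but nothing was recorded, and missing (NaN)
    outside the deployment window.  Records are expected to be
    independence-filtered already (not enforced: the daily OR makes the
    history insensitive to duplicated events within a day).

    Records at stations absent from the design raise a ``ValueError``;
    records dated outside a station's deployment window are ignored.
    """
    design = validate_design(design)
    stations = design["station_id"].tolist()
    station_index = {s: i for i, s in enumerate(stations)}
    starts = design["start_date"].to_numpy()
    n_occ = design["n_occasions"].to_numpy()
    K = int(n_occ.max())
    matrix = np.full((len(stations), K), np.nan)
    for i, k in enumerate(n_occ):
        matrix[i, :k] = 0.0

    members = set(guild_map.members(guild))
    recs = records[records["species"].isin(members)]
    unknown_stations = set(recs["station_id"]) - set(station_index)
    if unknown_stations:
        raise ValueError(
            f"records at stations absent from the design: {sorted(unknown_stations)}"
        )
    for station, t in zip(recs["station_id"], recs["timestamp"]):
        i = station_index[station]
        day = (t.normalize() - pd.Timestamp(starts[i])).days
        if 0 <= day < n_occ[i]:
            matrix[i, day] = 1.0
    return DetectionHistory(guild=guild, stations=stations, matrix=matrix)


def naive_occupancy(history: DetectionHistory) -> float:
    """Fraction of sites with at least one detection (no detection correction)."""
    if history.n_sites == 0:
        raise ValueError("naive occupancy is undefined with zero sites")
    detected = np.nansum(history.matrix, axis=1) > 0
    return float(detected.sum() / history.n_sites)


def write_detection_history(history: DetectionHistory, path) -> None:
    """Write a history as delimited text: rows = stations, entries 0/1/NA."""
    df = pd.DataFrame(
        history.matrix,
        index=pd.Index(history.stations, name="station_id"),
        columns=[f"occ_{j + 1}" for j in range(history.n_occasions)],
    )
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path)


def read_detection_history(path, guild: str) -> DetectionHistory:
    df = pd.read_csv(path, index_col="station_id", na_values=["NA"])
    return DetectionHistory(
        guild=guild, stations=[str(s) for s in df.index], matrix=df.to_numpy(float)
    )
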