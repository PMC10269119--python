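"""Spatiotemporal overlap from grid x hour detection matrices.

Independent detections of each guild are aggregated over the whole survey
into a grids x 24 count matrix; a guild's *activity cells* are the
(grid, hour-of-day) pairs where it was recorded at least once.  Overlap
statistics are computed on these cell sets:

- exclusive proportion: share of the focal guild's active cells where no
  other guild was ever active (denominator = the focal guild's cells);
- pairwise overlap: Jaccard proportion |A & B| / |A | B|;
- triple overlap: |A & B & C| / |A | B | C|.

Every reported statistic carries its numerator and denominator, because
alternative denominator conventions exist in the literature.  Uncertainty
comes from a seeded bootstrap that resamples grids (the independent
spatial units of the design) with replacement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import GuildMap

N_HOURS = 24


@dataclass
class GridHourCounts:
    guild: str
    grids: list[str]
    matrix: np.ndarray  # grids x 24 nonnegative ints

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.grids), N_HOURS):
            raise ValueError("grid-hour matrix must be (n_grids, 24)")
        if (self.matrix < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class ActivityCellSet:
    guild: str
    cells: frozenset  # of (grid_label, hour)


@dataclass
class OverlapSummary:
    """Exclusive / pairwise / triple overlap proportions with bootstrap CIs.

    ``stats`` maps a statistic name (e.g. ``exclusive[prey]``,
    ``pairwise[human,prey]``, ``triple``) to a dict holding the point
    proportion, its numerator and denominator, and bootstrap SE and 95%
    percentile interval.
    """

    stats: dict
    B: int
    seed: int
    unit: str = "grid"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, d in self.stats.items():
            rows.append({"statistic": name, **d, "B": self.B, "seed": self.seed})
        return pd.DataFrame(rows)


def build_grid_hour_counts(
    records: pd.DataFrame, design: pd.DataFrame, guild_map: GuildMap
) -> dict[str, GridHourCounts]:
    """Aggregate filtered records into one grids x 24 count matrix per guild.

    A record at a station not in the design, or dated outside the
    station's deployment window, raises a ``ValueError`` (the matrices are
    defined only over surveyed effort).
    """
    grids = list(dict.fromkeys(design["grid_label"]))
    grid_index = {g: i for i, g in enumerate(grids)}
    station_info = {
        row.station_id: (row.grid_label, row.start_date, int(row.n_occasions))
        for row in design.itertuples()
    }
    mats = {g: np.zeros((len(grids), N_HOURS), dtype=int) for g in guild_map.guilds}
    for row in records.itertuples():
        if row.species not in guild_map:
            continue
        if row.station_id not in station_info:
            raise ValueError(f"record at station {row.station_id!r} absent from design")
        grid, start, n_occ = station_info[row.station_id]
        day = (row.timestamp.normalize() - start).days
        if not 0 <= day < n_occ:
            raise ValueError(
                f"record at {row.station_id!r} on {row.timestamp} lies outside "
                "the deployment window"
            )
        mats[guild_map.guild_of(row.species)][grid_index[grid], row.timestamp.hour] += 1
    return {
        g: GridHourCounts(guild=g, grids=grids, matrix=m) for g, m in mats.items()
    }


def activity_cells(counts: GridHourCounts) -> ActivityCellSet:
    """Binarise a count matrix into the set of (grid, hour) active cells."""
    gi, hi = np.nonzero(counts.matrix)
    return ActivityCellSet(
        guild=counts.guild,
        cells=frozenset((counts.grids[g], int(h)) for g, h in zip(gi, hi)),
    )


def exclusive_proportion(focal: ActivityCellSet, others: Sequence[ActivityCellSet]) -> float:
    """Share of the focal guild's active cells where it was active alone."""
    if not focal.cells:
        raise ValueError("exclusive proportion is undefined for an empty focal set")
    union_others = frozenset().union(*(o.cells for o in others)) if others else frozenset()
    return len(focal.cells - union_others) / len(focal.cells)


def pairwise_overlap(a: ActivityCellSet, b: ActivityCellSet) -> float:
    """Jaccard overlap |A & B| / |A | B| of two guilds' active cells."""
    union = a.cells | b.cells
    if not union:
        raise ValueError("pairwise overlap is undefined when both sets are empty")
    return len(a.cells & b.cells) / len(union)


def triple_overlap(a: ActivityCellSet, b: ActivityCellSet, c: ActivityCellSet) -> float:
    """|A & B & C| / |A | B | C| over three guilds' active cells."""
    union = a.cells | b.cells | c.cells
    if not union:
        raise ValueError("triple overlap is undefined when all sets are empty")
    return len(a.cells & b.cells & c.cells) / len(union)


def venn_regions(a: ActivityCellSet, b: ActivityCellSet, c: ActivityCellSet) -> dict:
    """Counts of the 7 exclusive regions of the 3-set partition, keyed by
    membership pattern '100'.. '111' in (a, b, c) order.  The counts sum
    to |A | B | C|."""
    regions = {f"{i:03b}": 0 for i in range(1, 8)}
    for cell in a.cells | b.cells | c.cells:
        key = f"{int(cell in a.cells)}{int(cell in b.cells)}{int(cell in c.cells)}"
        regions[key] += 1
    return regions


def _stats_from_cells(cells_by_guild: Mapping[str, frozenset]) -> dict:
    """Point statistics (with numerator/denominator) from per-guild cell sets."""
    guilds = list(cells_by_guild)
    out: dict[str, dict] = {}
    for g in guilds:
        focal = cells_by_guild[g]
        others = frozenset().union(*(cells_by_guild[o] for o in guilds if o != g))
        num, den = len(focal - others), len(focal)
        out[f"exclusive[{g}]"] = {
            "numerator": num,
            "denominator": den,
            "proportion": num / den if den else np.nan,
        }
    for g1, g2 in itertools.combinations(guilds, 2):
        inter = len(cells_by_guild[g1] & cells_by_guild[g2])
        union = len(cells_by_guild[g1] | cells_by_guild[g2])
        out[f"pairwise[{g1},{g2}]"] = {
            "numerator": inter,
            "denominator": union,
            "proportion": inter / union if union else np.nan,
        }
    if len(guilds) >= 3:
        inter = len(frozenset.intersection(*(cells_by_guild[g] for g in guilds[:3])))
        union = len(frozenset.union(*(cells_by_guild[g] for g in guilds[:3])))
        out["triple"] = {
            "numerator": inter,
            "denominator": union,
            "proportion": inter / union if union else np.nan,
        }
    return out


def bootstrap_spatiotemporal(
    records: pd.DataFrame,
    design: pd.DataFrame,
    guild_map: GuildMap,
    B: int = 1000,
    seed: int = 0,
) -> OverlapSummary:
    """Grid-level bootstrap of all spatiotemporal overlap statistics.

    Grids are resampled with replacement (each draw carries the grid's
    full record set as a distinct pseudo-grid); every statistic is
    recomputed per resample, giving bootstrap SEs and 95% percentile
    intervals.  Resamples where a statistic is undefined (e.g. an empty
    focal set) contribute NaN and are dropped from its percentiles.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    counts = build_grid_hour_counts(records, design, guild_map)
    grids = next(iter(counts.values())).grids
    if len(grids) < 5:
        raise ValueError("grid bootstrap needs at least 5 grids")
    guilds = list(counts)
    cells0 = {g: activity_cells(counts[g]).cells for g in guilds}
    point = _stats_from_cells(cells0)

    # per-grid hour sets, so resamples are cheap set unions
    hours_by_grid = {
        g: [frozenset(np.nonzero(counts[g].matrix[i])[0].tolist()) for i in range(len(grids))]
        for g in guilds
    }
    rng = np.random.default_rng(seed)
    names = list(point)
    draws = {name: np.empty(B) for name in names}
    for b in range(B):
        idx = rng.integers(0, len(grids), len(grids))
        cells = {
            g: frozenset(
                (pos, h) for pos, i in enumerate(idx) for h in hours_by_grid[g][i]
            )
            for g in guilds
        }
        stats_b = _stats_from_cells(cells)
        for name in names:
            draws[name][b] = stats_b[name]["proportion"]

    stats = {}
    for name in names:
        d = draws[name]
        valid = d[~np.isnan(d)]
        entry = dict(point[name])
        if valid.size:
            lo, hi = np.percentile(valid, [2.5, 97.5])
            entry.update(
                se=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
                ci_low=float(lo),
                ci_high=float(hi),
            )
        else:
            entry.update(se=np.nan, ci_low=np.nan, ci_high=np.nan)
        stats[name] = entry
    return OverlapSummary(stats=stats, B=B, seed=seed, unit="grid")
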