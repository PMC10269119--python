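"""Seeded synthetic camera-trap surveys with known ground truth.

The generator draws guild-level latent presence from the same
multinomial-logit state distribution the occupancy model fits, then turns
presence into timestamped records through a Poisson encounter process:
for every occupied (grid, species, day) the number of events is
Poisson(lambda_species) and each event's clock time is drawn from the
species' von Mises diel mixture.  One mechanism therefore yields both
day-level detection histories (occupancy) and event times (activity and
spatiotemporal overlap); the per-occasion detection probability it
implies, p_guild = 1 - exp(-sum of member lambdas), is reported so
recovery tests have exact truth.  Unoccupied sites never produce records.

All randomness flows from one root seed through named substreams
(presence, counts, times), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize

from .occupancy import NaturalParams, enumerate_states, state_probabilities
from .records import TIMESTAMP_FORMAT, DetectionHistory, GuildMap

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class DielComponent:
    """One von Mises component of a diel mixture (mean in clock hours)."""

    mean_hour: float
    kappa: float
    weight: float


@dataclass(frozen=True)
class SpeciesProfile:
    """Species-level encounter process: guild, daily encounter rate at an
    occupied site (events / site-day) and diel mixture."""

    name: str
    guild: str
    daily_rate: float
    diel: tuple[DielComponent, ...]

    def __post_init__(self) -> None:
        if self.daily_rate <= 0:
            raise ValueError(f"{self.name}: daily encounter rate must be positive")
        w = sum(c.weight for c in self.diel)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: diel mixture weights must sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_grids: int
    n_days: int
    guild_names: tuple[str, ...]
    f: NaturalParams
    species: tuple[SpeciesProfile, ...]
    seed: int = 0
    start_date: str = "2015-12-15"

    def __post_init__(self) -> None:
        if self.n_grids < 5:
            raise ValueError("need at least 5 grids")
        if self.n_days < 1:
            raise ValueError("need at least 1 survey day")
        bad = [sp.name for sp in self.species if sp.guild not in self.guild_names]
        if bad:
            raise ValueError(f"species with unknown guilds: {bad}")

    def guild_map(self) -> GuildMap:
        return GuildMap({sp.name: sp.guild for sp in self.species})

    def guild_rate(self, guild: str) -> float:
        return sum(sp.daily_rate for sp in self.species if sp.guild == guild)

    def implied_detection_prob(self, guild: str) -> float:
        """Per-occasion guild detection probability at an occupied site
        under the Poisson encounter process: p = 1 - exp(-sum lambdas)."""
        return float(1.0 - np.exp(-self.guild_rate(guild)))

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["f"] = {
            "first_order": self.f.first_order.tolist(),
            "second_order": None
            if self.f.second_order is None
            else self.f.second_order.tolist(),
        }
        d["guild_names"] = list(self.guild_names)
        d["species"] = [asdict(sp) | {"diel": [asdict(c) for c in sp.diel]} for sp in self.species]
        return d


@dataclass
class SimulationTruth:
    """Ground-truth ledger: latent presence plus the echoed configuration."""

    config: SimulationConfig
    z: np.ndarray  # n_grids x S in {0, 1}
    detection_probs: dict[str, float]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    presence, counts, times = np.random.SeedSequence(seed).spawn(3)
    return {
        "presence": np.random.default_rng(presence),
        "counts": np.random.default_rng(counts),
        "times": np.random.default_rng(times),
    }


def simulate_presence(config: SimulationConfig, rng=None) -> np.ndarray:
    """Draw each grid's guild-presence vector iid from the multinomial-logit
    state distribution of the configured natural parameters."""
    rng = _rngs(config.seed)["presence"] if rng is None else rng
    dist = state_probabilities(config.f)
    states = enumerate_states(config.f.S)
    return states[rng.choice(states.shape[0], size=config.n_grids, p=dist)]


def _station_label(i: int) -> str:
    return f"St{i + 1:03d}"


def _grid_label(i: int) -> str:
    return f"G{i + 1:03d}"


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Concurrent survey design: one station per 1-km2 grid cell."""
    return pd.DataFrame(
        {
            "station_id": [_station_label(i) for i in range(config.n_grids)],
            "grid_label": [_grid_label(i) for i in range(config.n_grids)],
            "start_date": pd.Timestamp(config.start_date),
            "n_occasions": config.n_days,
        }
    )


def simulate_events(z: np.ndarray, config: SimulationConfig, rngs=None) -> pd.DataFrame:
    """Poisson encounter process on occupied (grid, species, day) triples.

    Event clock times follow the species' diel von Mises mixture; records
    are shuffled, then stably sorted by timestamp, so tied-time ordering
    is seeded rather than generation-order dependent.
    """
    if rngs is None:
        rngs = _rngs(config.seed)
    rc, rt = rngs["counts"], rngs["times"]
    start = pd.Timestamp(config.start_date)
    gidx = {g: i for i, g in enumerate(config.guild_names)}
    rows: list[tuple] = []
    for sp in config.species:
        occupied = np.flatnonzero(z[:, gidx[sp.guild]])
        if occupied.size == 0:
            continue
        counts = rc.poisson(sp.daily_rate, size=(occupied.size, config.n_days))
        weights = np.array([c.weight for c in sp.diel])
        means = np.array([c.mean_hour for c in sp.diel]) / 24.0 * TWO_PI
        kappas = np.array([c.kappa for c in sp.diel])
        total = int(counts.sum())
        if total == 0:
            continue
        comp = rt.choice(len(weights), size=total, p=weights)
        angles = (rt.vonmises(means[comp], kappas[comp]) % TWO_PI)
        secs = np.floor(angles / TWO_PI * 86400.0).astype(int)
        cameras = rt.integers(1, 3, size=total)
        e = 0
        for gi, site in enumerate(occupied):
            for day in range(config.n_days):
                for _ in range(counts[gi, day]):
                    ts = start + pd.Timedelta(days=day, seconds=int(secs[e]))
                    rows.append((_station_label(site), sp.name, ts, f"C{cameras[e]}"))
                    e += 1
    df = pd.DataFrame(rows, columns=["station_id", "species", "timestamp", "camera_id"])
    if len(df):
        perm = rt.permutation(len(df))
        df = df.iloc[perm].sort_values("timestamp", kind="mergesort")
    return df.reset_index(drop=True)


def simulate_survey(config: SimulationConfig):
    """Full survey draw: (records, design, truth)."""
    rngs = _rngs(config.seed)
    z = simulate_presence(config, rngs["presence"])
    records = simulate_events(z, config, rngs)
    design = make_design(config)
    truth = SimulationTruth(
        config=config,
        z=z,
        detection_probs={g: config.implied_detection_prob(g) for g in config.guild_names},
    )
    return records, design, truth


# ---------------------------------------------------------------------------
# Survey-scale preset emulating the study system
# ---------------------------------------------------------------------------

#: target guild-level marginal occupancies for (prey, predator, human)
PRESET_MARGINALS = (0.78, 0.42, 0.38)
#: fixed second-order truth: prey-predator 0, prey-human positive (the
#: human-shield signal), predator-human ~ 0
PRESET_SECOND_ORDER = (0.0, 1.25, 0.0)

#: species encounter rates (events per occupied site-day) and diel
#: mixtures: humans/spotted deer/wild boar diurnal, tiger/sambar
#: nocturnal, leopard/barking deer crepuscular.
PRESET_SPECIES = (
    SpeciesProfile("spotted deer", "prey", 0.35, (DielComponent(10.5, 1.2, 1.0),)),
    SpeciesProfile("wild boar", "prey", 0.10, (DielComponent(14.5, 1.5, 1.0),)),
    SpeciesProfile(
        "barking deer",
        "prey",
        0.10,
        (DielComponent(6.5, 3.0, 0.5), DielComponent(17.5, 3.0, 0.5)),
    ),
    SpeciesProfile("sambar deer", "prey", 0.10, (DielComponent(23.0, 1.2, 1.0),)),
    SpeciesProfile("tiger", "predator", 0.11, (DielComponent(1.0, 1.5, 1.0),)),
    SpeciesProfile(
        "leopard",
        "predator",
        0.07,
        (DielComponent(5.5, 3.0, 0.5), DielComponent(18.5, 3.0, 0.5)),
    ),
    SpeciesProfile("human", "human", 1.60, (DielComponent(12.0, 2.5, 1.0),)),
)


@lru_cache(maxsize=None)
def _solve_first_order(targets: tuple, second_order: tuple) -> tuple:
    """Invert the state distribution: find first-order parameters whose
    marginals equal ``targets`` given fixed pairwise parameters."""
    targets_arr = np.asarray(targets)
    S = targets_arr.size
    states = enumerate_states(S)
    f2 = np.asarray(second_order)

    def resid(f1):
        dist = state_probabilities(NaturalParams(f1, f2))
        return states.T @ dist - targets_arr

    sol = optimize.root(resid, np.zeros(S), method="hybr", tol=1e-13)
    if not sol.success or np.abs(resid(sol.x)).max() > 1e-8:
        raise RuntimeError(f"marginal inversion failed: {sol.message}")
    return tuple(sol.x)


def paper_like_preset(
    n_grids: int = 88, n_days: int = 20, seed: int = 0
) -> SimulationConfig:
    """Survey-scale preset: 88 one-km2 grids surveyed 20 concurrent days,
    guild marginal occupancies (0.78, 0.42, 0.38) for (prey, predator,
    human), a positive human-prey co-occurrence interaction and zero
    predator interactions, and species-specific diel activity.  The
    first-order parameters are obtained by deterministic numerical
    inversion of the state distribution, so the preset is byte-stable.
    """
    f1 = np.array(_solve_first_order(PRESET_MARGINALS, PRESET_SECOND_ORDER))
    return SimulationConfig(
        n_grids=n_grids,
        n_days=n_days,
        guild_names=("prey", "predator", "human"),
        f=NaturalParams(f1, np.array(PRESET_SECOND_ORDER)),
        species=PRESET_SPECIES,
        seed=seed,
    )


def simulate_histories(
    f: NaturalParams,
    p,
    n_sites: int,
    n_occasions: int,
    guild_names,
    seed: int = 0,
) -> dict[str, DetectionHistory]:
    """Direct history-level draw (z from the state distribution, then
    occasion-wise Bernoulli detections with given per-guild p); the fast
    path for occupancy parameter-recovery studies."""
    rng = np.random.default_rng(seed)
    states = enumerate_states(f.S)
    dist = state_probabilities(f)
    z = states[rng.choice(states.shape[0], size=n_sites, p=dist)]
    p = np.asarray(p, float)
    out = {}
    for s, g in enumerate(guild_names):
        y = rng.random((n_sites, n_occasions)) < (p[s] * z[:, s])[:, None]
        out[g] = DetectionHistory(
            guild=g,
            stations=[_station_label(i) for i in range(n_sites)],
            matrix=y.astype(float),
        )
    return out


def write_fixture(config: SimulationConfig, out_dir) -> dict[str, pathlib.Path]:
    """Write records.csv, design.csv and truth.json for a configuration;
    rerunning with the same seed reproduces byte-identical files."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, design, truth = simulate_survey(config)
    paths = {
        "records": out / "records.csv",
        "design": out / "design.csv",
        "truth": out / "truth.json",
    }
    rec = records.copy()
    rec["timestamp"] = rec["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    rec.to_csv(paths["records"], index=False)
    des = design.copy()
    des["start_date"] = des["start_date"].dt.strftime("%Y-%m-%d")
    des.to_csv(paths["design"], index=False)
    payload = {
        "config": config.to_jsonable(),
        "z": truth.z.tolist(),
        "detection_probs": truth.detection_probs,
    }
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths


def config_from_json(payload: dict) -> SimulationConfig:
    """Rebuild a SimulationConfig from the truth.json payload."""
    c = payload["config"] if "config" in payload else payload
    f = NaturalParams(
        np.array(c["f"]["first_order"]),
        None if c["f"]["second_order"] is None else np.array(c["f"]["second_order"]),
    )
    species = tuple(
        SpeciesProfile(
            sp["name"],
            sp["guild"],
            sp["daily_rate"],
            tuple(DielComponent(**comp) for comp in sp["diel"]),
        )
        for sp in c["species"]
    )
    return SimulationConfig(
        n_grids=c["n_grids"],
        n_days=c["n_days"],
        guild_names=tuple(c["guild_names"]),
        f=f,
        species=species,
        seed=c["seed"],
        start_date=c["start_date"],
    )
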