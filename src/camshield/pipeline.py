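"""Configuration-driven orchestration of the full analysis.

A single YAML (or dict) configuration names either input files (records +
design) or a simulation block, and the pipeline runs: independence filter
-> survey effort and naive occupancy -> guild detection histories ->
MSOM fits with AIC comparison -> marginal / pairwise / conditional
occupancy table -> diel activity overlap table -> spatiotemporal overlap
summary and Venn region counts.  Every output carries the seed and the
configuration hash; a run manifest records versions and wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import bootstrap_overlap_ci, density_grid_frame, records_to_sample
from .occupancy import (
    MSOMSpec,
    compare_models,
    conditional_occupancy,
    cooccurrence_probability,
    fit_msom,
    marginal_occupancy,
)
from .records import (
    DEFAULT_GUILD_MAP,
    GuildMap,
    build_detection_history,
    filter_independent,
    naive_occupancy,
    read_design,
    read_records,
)
from .simulate import config_from_json, paper_like_preset, simulate_survey, write_fixture
from .spatiotemporal import bootstrap_spatiotemporal, build_grid_hour_counts, venn_regions, activity_cells

log = logging.getLogger("camshield")

DEFAULT_CONFIG = {
    "independence_window_minutes": 15.0,
    "bootstrap": {"B": 1000},
    "seed": 0,
    "msom": {"orders": [1, 2]},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline configuration must be a mapping")
    return cfg


def config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def summarize_effort(design: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Survey effort and per-species capture summary.

    Trap-nights = sum over stations of their occasions; per species, the
    number of (independent) captures and the naive occupancy (fraction of
    stations with >= 1 record); a TOTAL row sums captures.
    """
    trap_nights = int(design["n_occasions"].sum())
    n_stations = design["station_id"].nunique()
    rows = []
    for sp, grp in records.groupby("species", sort=True):
        rows.append(
            {
                "species": sp,
                "n_captures": len(grp),
                "naive_occupancy": grp["station_id"].nunique() / n_stations,
                "trap_nights": trap_nights,
            }
        )
    rows.append(
        {
            "species": "TOTAL",
            "n_captures": len(records),
            "naive_occupancy": np.nan,
            "trap_nights": trap_nights,
        }
    )
    return pd.DataFrame(rows)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def _load_inputs(config: dict, out: pathlib.Path):
    if "simulate" in config:
        sim = config["simulate"] or {}
        if "truth_json" in sim:
            sim_config = config_from_json(json.loads(pathlib.Path(sim["truth_json"]).read_text()))
        else:
            sim_config = paper_like_preset(
                n_grids=sim.get("n_grids", 88),
                n_days=sim.get("n_days", 20),
                seed=sim.get("seed", config.get("seed", 0)),
            )
        records, design, _truth = simulate_survey(sim_config)
        write_fixture(sim_config, out / "simulated")
        log.info("simulated %d records at %d grids", len(records), sim_config.n_grids)
        return records, design
    if "records" not in config or "design" not in config:
        raise ValueError("config must contain either a 'simulate' block or 'records' + 'design' paths")
    records = read_records(config["records"])
    design = read_design(config["design"])
    log.info("read %d records, %d stations", len(records), len(design))
    return records, design


def run(config: Mapping, out_dir) -> dict:
    """Execute the full pipeline; returns the map of written output paths.

    Any stage failure aborts with the stage name; outputs of completed
    stages are preserved on disk.
    """
    t0 = time.time()
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    seed = int(cfg["seed"])
    B = int(cfg["bootstrap"].get("B", 1000))
    if B < 100:
        raise ValueError("bootstrap B must be at least 100")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    guild_map = (
        GuildMap(dict(cfg["guild_map"])) if "guild_map" in cfg else DEFAULT_GUILD_MAP
    )
    paths: dict[str, pathlib.Path] = {}
    counts_log: dict[str, int] = {}

    def _write(name, frame: pd.DataFrame):
        frame = frame.copy()
        frame["seed"] = seed
        frame["config_hash"] = chash
        p = out / name
        frame.to_csv(p, index=False)
        paths[name] = p
        return p

    records, design = _stage("inputs")(_load_inputs)(cfg, out)
    counts_log["raw_records"] = len(records)

    window = float(cfg["independence_window_minutes"])
    filtered = _stage("filter")(filter_independent)(records, window)
    counts_log["independent_records"] = len(filtered)
    log.info("independence filter (%g min): %d -> %d records", window, len(records), len(filtered))

    effort = _stage("effort")(summarize_effort)(design, filtered)
    _write("effort.csv", effort)

    @_stage("histories")
    def _histories():
        hs = {}
        rows = []
        for g in guild_map.guilds:
            h = build_detection_history(filtered, design, guild_map, g)
            hs[g] = h
            rows.append({"guild": g, "naive_occupancy": naive_occupancy(h)})
        return hs, pd.DataFrame(rows)

    histories, naive = _histories()
    _write("naive_occupancy.csv", naive)

    @_stage("occupancy")
    def _occupancy():
        orders = cfg["msom"].get("orders", [1, 2])
        fits = [
            fit_msom(histories, MSOMSpec(guild_map.guilds, interaction_order=o), seed=seed)
            for o in orders
        ]
        ranking = compare_models(fits)
        best = fits[ranking[0]["model"]]
        payload = {
            "ranking": ranking,
            "fits": [f.to_dict() for f in fits],
            "seed": seed,
            "config_hash": chash,
        }
        p = out / "msom_fits.json"
        p.write_text(json.dumps(payload, indent=2))
        paths["msom_fits.json"] = p

        guilds = guild_map.guilds
        rows = []

        def add(kind, g, other, est):
            rows.append(
                {
                    "quantity": kind,
                    "guild": g,
                    "given": other,
                    "estimate": est.value,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )

        for g in guilds:
            add("marginal", g, "", marginal_occupancy(best, g))
        if "human" in guilds:
            for g in guilds:
                if g == "human":
                    continue
                add("cooccurrence_with_human", g, "human", cooccurrence_probability(best, g, "human"))
                if best.spec.interaction_order == 2:
                    add("conditional_on_human_present", g, "human",
                        conditional_occupancy(best, g, "human", present=True))
                    add("conditional_on_human_absent", g, "human",
                        conditional_occupancy(best, g, "human", present=False))
        _write("occupancy_estimates.csv", pd.DataFrame(rows))
        return best

    _occupancy()

    @_stage("activity")
    def _activity():
        pairs = cfg.get("activity_pairs")
        if pairs is None:
            others = [s for s in guild_map.species if s != "human"]
            pairs = [["human", s] for s in others]
        rows, grids = [], []
        for a, b in pairs:
            sa = records_to_sample(filtered, a)
            sb = records_to_sample(filtered, b)
            if sa.n < 2 or sb.n < 2:
                log.warning("skipping activity pair (%s, %s): too few events", a, b)
                continue
            res = bootstrap_overlap_ci(sa, sb, B=B, seed=seed)
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "n_a": res.n1,
                    "n_b": res.n2,
                    "estimator": res.estimator,
                    "delta": res.delta,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "classification": res.classification,
                    "B": res.B,
                }
            )
            g = density_grid_frame(sa, sb)
            g.insert(0, "pair", f"{a}|{b}")
            grids.append(g.rename(columns=lambda c: c.replace(a, "a").replace(b, "b")))
        _write("activity_overlap.csv", pd.DataFrame(rows))
        if grids:
            _write("density_grids.csv", pd.concat(grids, ignore_index=True))

    _activity()

    @_stage("spatiotemporal")
    def _spatiotemporal():
        summary = bootstrap_spatiotemporal(filtered, design, guild_map, B=B, seed=seed)
        _write("spatiotemporal.csv", summary.to_frame())
        counts = build_grid_hour_counts(filtered, design, guild_map)
        guilds = guild_map.guilds
        if len(guilds) >= 3:
            cells = [activity_cells(counts[g]) for g in guilds[:3]]
            regions = venn_regions(*cells)
            payload = {"guild_order": list(guilds[:3]), "regions": regions,
                       "seed": seed, "config_hash": chash}
            p = out / "venn_regions.json"
            p.write_text(json.dumps(payload, indent=2))
            paths["venn_regions.json"] = p

    _spatiotemporal()

    manifest = {
        "config": dict(cfg),
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "record_counts": counts_log,
        "wall_time_s": round(time.time() - t0, 3),
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest.json"] = p
    log.info("pipeline complete in %.1f s; outputs in %s", time.time() - t0, out)
    return paths
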