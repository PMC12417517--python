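"""End-to-end pipeline: from a city dataset (real files or the synthetic
generator) to distance tables, benefit profile, radius search, and the
placement-improvement experiment.

Artifacts written to the output directory:

* ``table2.csv`` — seven-number summary of inter-device nearest-neighbour
  straight-line distances;
* ``table3.csv`` — event-to-nearest-device distances, straight-line and
  walking-route rows;
* ``table4.csv`` — benefit profile (AVG and % rows) over the radius grid,
  plus the golden-window walking column and the target-state column;
* ``radius_search.csv`` / ``best_radius.json`` — objective curve and optimum;
* ``placement.json`` — the improvement experiment;
* ``profile.png``, ``objective.png``, ``city.png``, ``placement.png``;
* ``manifest.json`` — config echo, seed, input checksums, per-stage counts.

All randomness flows from one root seed through per-stage spawned streams,
so stages are independently rerunnable and two runs with the same seed
produce identical CSV bytes.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (DEFAULT_RADII, TargetState, benefit_profile,
                       golden_window_coverage, summarize_distances,
                       type_cross_table)
from .geo import Projection, nearest_to, nearest_neighbor_distances
from .io import (file_checksum, read_network, read_points, read_region_geojson,
                 write_network_geojson, write_points_csv, write_region_geojson)
from .network import WalkWindow, route_pair_distances
from .optimize import search
from .placement import PlacementConfig, run_experiment
from .plots import plot_city, plot_objective, plot_placement, plot_profile
from .synth import CityConfig, SyntheticCity, generate_city

#: Default projection reference: the modelled urban core's approximate centre.
DEFAULT_PROJECTION = Projection(ref_lon=117.184, ref_lat=34.261)

#: Route distances beyond this cutoff are treated as unreachable in table 3.
ROUTE_CUTOFF_M = 10_000.0


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; either ``synthetic`` or file ``inputs``."""

    output_dir: str = "out"
    seed: int = 0
    synthetic: dict | None = None            # CityConfig fields
    events_path: str | None = None
    devices_path: str | None = None
    network_edges_path: str | None = None
    network_nodes_path: str | None = None
    region_path: str | None = None
    projection: Projection = DEFAULT_PROJECTION
    radii: tuple = DEFAULT_RADII
    window: WalkWindow = WalkWindow()
    target: TargetState = TargetState()
    placement: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("output_dir", "seed", "synthetic", "events_path", "devices_path",
                    "network_edges_path", "network_nodes_path", "region_path"):
            if key in raw:
                kwargs[key] = raw[key]
        if "projection" in raw:
            kwargs["projection"] = Projection(**raw["projection"])
        if "radii" in raw:
            r = raw["radii"]
            kwargs["radii"] = tuple(range(int(r["start"]), int(r["stop"]) + 1,
                                          int(r["step"]))) if isinstance(r, dict) else tuple(r)
        if "walk_window" in raw:
            kwargs["window"] = WalkWindow(**raw["walk_window"])
        if "target" in raw:
            kwargs["target"] = TargetState(target_avg=raw["target"].get("avg", 1.0),
                                           target_pct=raw["target"].get("pct", 40.0))
        if "placement" in raw:
            kwargs["placement"] = raw["placement"]
        return cls(**kwargs)


def _load_city(config: RunConfig) -> tuple[SyntheticCity, dict]:
    """Materialise the city either from the generator or from input files."""
    checksums = {}
    if config.synthetic is not None or config.events_path is None:
        city_cfg = CityConfig(**{**(config.synthetic or {}), "seed": config.seed})
        return generate_city(city_cfg), checksums
    proj = config.projection
    events, ev_report = read_points(config.events_path, "events", proj)
    devices, dv_report = read_points(config.devices_path, "devices", proj)
    region = read_region_geojson(config.region_path, proj)
    graph = read_network(config.network_edges_path, config.network_nodes_path,
                         proj).largest_component()
    for key, p in (("events", config.events_path), ("devices", config.devices_path),
                   ("region", config.region_path), ("network", config.network_edges_path)):
        checksums[key] = file_checksum(p)
    city = SyntheticCity(graph=graph, events=events, devices=devices, region=region,
                         truth={"source": "files", "seed": config.seed,
                                "events_malformed": len(ev_report),
                                "devices_malformed": len(dv_report)})
    return city, checksums


def _summary_frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame({name: s.to_row() for name, s in rows.items()}).T


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write all artifacts; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "started": dt.datetime.now().isoformat(timespec="seconds"),
        "status": "running",
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k not in ("projection", "window", "target")},
        "stages": {},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    city, checksums = _load_city(config)
    manifest["input_checksums"] = checksums
    event_xy, device_xy = city.event_xy, city.device_xy
    manifest["stages"]["load"] = {"n_events": len(city.events),
                                  "n_devices": len(city.devices)}

    write_points_csv(city.events, out / "events.csv", config.projection)
    write_points_csv(city.devices, out / "devices.csv", config.projection)
    write_region_geojson(city.region, out / "region.geojson", config.projection)
    write_network_geojson(city.graph, out / "network.geojson", config.projection)

    # location-type cross table
    type_cross_table(city.events, city.devices).to_csv(out / "table1.csv")

    # table 2: inter-device nearest-neighbour straight-line distances
    dev_nn = nearest_neighbor_distances(device_xy)
    _summary_frame({"Distance": summarize_distances(dev_nn)}).to_csv(out / "table2.csv")

    # table 3: event -> nearest device, straight-line and walking-route
    straight, nearest_idx = nearest_to(event_xy, device_xy)
    # per-pair cutoff: generous multiple of the straight distance keeps each
    # Dijkstra local; anything beyond is treated as unreachable and excluded
    route = route_pair_distances(event_xy, device_xy[nearest_idx], city.graph,
                                 cutoff=np.minimum(4 * straight + 500, ROUTE_CUTOFF_M))
    reachable = np.isfinite(route)
    manifest["stages"]["table3"] = {
        "n_pairs": len(route),
        "n_unreachable_excluded": int((~reachable).sum()),
        "median_route_straight_ratio": float(np.median(
            route[reachable & (straight > 0)] / straight[reachable & (straight > 0)])),
    }
    _summary_frame({
        "Straight-line": summarize_distances(straight),
        "Walking-route": summarize_distances(route[reachable]),
    }).to_csv(out / "table3.csv")

    # table 4: benefit profile + golden-window walking column + target column
    profile = benefit_profile(event_xy, device_xy, config.radii)
    gw_pct, gw_avg, _ = golden_window_coverage(event_xy, device_xy, city.graph,
                                               config.window)
    table4 = pd.DataFrame(
        [list(np.round(profile.avg_devices, 2)) + [round(gw_avg, 2),
                                                   config.target.target_avg],
         list(np.round(profile.pct_covered, 2)) + [round(gw_pct, 2),
                                                   config.target.target_pct]],
        index=["AVG", "%"],
        columns=[f"{int(r)} m" for r in profile.radii] + ["3 min (W)", "Standard"],
    )
    table4.to_csv(out / "table4.csv")
    manifest["stages"]["profile"] = {"golden_window_pct": gw_pct,
                                     "golden_window_avg": gw_avg}

    # radius search
    result = search(profile, config.target)
    result.curve.to_csv(out / "radius_search.csv", index=False)
    (out / "best_radius.json").write_text(json.dumps({
        "best_radius_m": result.best_radius,
        "best_score": result.best_score,
        "band_m": list(result.band),
        "target": dataclasses.asdict(result.target),
    }, indent=2))

    # placement experiment
    seed_placement = int(np.random.SeedSequence(config.seed).spawn(4)[3]
                         .generate_state(1)[0] % (2 ** 31))
    pl_cfg = PlacementConfig(region=city.region, seed=seed_placement,
                             **config.placement)
    outcome = run_experiment(device_xy, pl_cfg, events=event_xy)
    placement = {
        "baseline_area_km2": outcome.baseline_area_km2,
        "simulated_area_km2": outcome.simulated_area_km2,
        "improvement": round(outcome.improvement, 4),
        "constraint_ok": bool(outcome.constraint_ok),
        "baseline_pct": outcome.baseline_pct,
        "simulated_pct": outcome.simulated_pct,
        "n_points": pl_cfg.n_points,
        "band_m": [pl_cfg.band_low, pl_cfg.band_high],
        "coverage_radius_m": pl_cfg.coverage_radius,
    }
    (out / "placement.json").write_text(json.dumps(placement, indent=2))
    manifest["stages"]["placement"] = {"improvement": placement["improvement"]}

    plot_profile(profile, config.target, out / "profile.png")
    plot_objective(result, out / "objective.png")
    plot_city(event_xy, device_xy, city.region, out / "city.png")
    plot_placement(outcome, pl_cfg.coverage_radius, city.region, out / "placement.png")

    manifest["status"] = "finished"
    manifest["finished"] = dt.datetime.now().isoformat(timespec="seconds")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
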