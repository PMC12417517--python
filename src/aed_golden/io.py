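"""Readers and writers: CSV and GeoJSON points, region polygons, road
networks, and run manifests.

Geographic files always carry (lon, lat) in decimal degrees; planar metre
coordinates are derived through a :class:`~aed_golden.geo.Projection` at read
time and never serialised.  Malformed rows are collected with line numbers
and reported, never silently dropped; a read aborts when more than 1% of
rows are malformed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .geo import Projection, project, unproject
from .network import RoadGraph

MALFORMED_ABORT_FRACTION = 0.01


class MalformedInputError(ValueError):
    """Raised when an input file has too many malformed rows; carries the
    per-row report."""

    def __init__(self, message: str, report: list):
        super().__init__(message)
        self.report = report


def _validate_lonlat(lon, lat) -> bool:
    try:
        lon, lat = float(lon), float(lat)
    except (TypeError, ValueError):
        return False
    return np.isfinite(lon) and np.isfinite(lat) and -180 <= lon <= 180 and -90 <= lat <= 90


def read_points(path, kind: str = "events",
                projection: Projection | None = None) -> tuple[pd.DataFrame, list]:
    """Read an event or device table from CSV or GeoJSON.

    CSV needs ``lon, lat`` columns, optionally ``loc_type`` and ``time``
    (events) or ``available_from``/``available_to`` (devices).  GeoJSON must
    be a FeatureCollection of Points with the same fields as properties.
    Returns (dataframe, malformed-row report); when a projection is given,
    planar ``x, y`` columns are added.
    """
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        with open(path) as fh:
            fc = json.load(fh)
        rows = []
        for i, feat in enumerate(fc.get("features", [])):
            props = dict(feat.get("properties") or {})
            geom = feat.get("geometry") or {}
            coords = geom.get("coordinates", [None, None])
            rows.append({"lon": coords[0], "lat": coords[1], **props})
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    missing = {"lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    report = []
    ok = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        if not _validate_lonlat(row["lon"], row["lat"]):
            ok[i] = False
            report.append({"row": int(i) + 1, "reason": "invalid lon/lat",
                           "lon": row["lon"], "lat": row["lat"]})
    if len(df) and len(report) / len(df) > MALFORMED_ABORT_FRACTION:
        raise MalformedInputError(
            f"{path}: {len(report)}/{len(df)} rows malformed (> "
            f"{MALFORMED_ABORT_FRACTION:.0%} threshold)", report)
    df = df.loc[ok].reset_index(drop=True)
    df["lon"] = df["lon"].astype(float)
    df["lat"] = df["lat"].astype(float)
    if "loc_type" not in df.columns:
        df["loc_type"] = "community"
    if kind == "devices":
        if "available_from" not in df.columns:
            df["available_from"] = "06:00"
        if "available_to" not in df.columns:
            df["available_to"] = "19:00"
    if projection is not None:
        xy = project(df[["lon", "lat"]].to_numpy(), projection)
        df["x"], df["y"] = xy[:, 0], xy[:, 1]
    return df, report


def write_points_csv(df: pd.DataFrame, path, projection: Projection | None = None) -> None:
    """Write a point table as CSV with lon/lat (derived from x/y if needed)."""
    out = df.copy()
    if "lon" not in out.columns:
        if projection is None:
            raise ValueError("projection required to derive lon/lat from planar coordinates")
        ll = unproject(out[["x", "y"]].to_numpy(), projection)
        out.insert(0, "lat", ll[:, 1])
        out.insert(0, "lon", ll[:, 0])
    out.drop(columns=[c for c in ("x", "y") if c in out.columns]).to_csv(path, index=False)


def write_points_geojson(df: pd.DataFrame, path,
                         projection: Projection | None = None) -> None:
    """Write a point table as an RFC 7946 FeatureCollection."""
    out = df.copy()
    if "lon" not in out.columns:
        if projection is None:
            raise ValueError("projection required to derive lon/lat from planar coordinates")
        ll = unproject(out[["x", "y"]].to_numpy(), projection)
        out["lon"], out["lat"] = ll[:, 0], ll[:, 1]
    features = []
    prop_cols = [c for c in out.columns if c not in ("lon", "lat", "x", "y")]
    for _, row in out.iterrows():
        props = {c: (str(row[c]) if isinstance(row[c], pd.Timestamp) else row[c])
                 for c in prop_cols}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row["lon"], row["lat"]]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_region_geojson(path, projection: Projection | None = None) -> Polygon:
    """Read a region polygon; projected to planar metres when a projection is given."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = shape(gj["features"][0]["geometry"])
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if projection is None:
        return geom
    ext = project(np.asarray(geom.exterior.coords), projection)
    holes = [project(np.asarray(ring.coords), projection) for ring in geom.interiors]
    return Polygon(ext, holes)


def write_region_geojson(region: Polygon, path, projection: Projection | None = None) -> None:
    geom = region
    if projection is not None:
        ext = unproject(np.asarray(region.exterior.coords), projection)
        holes = [unproject(np.asarray(r.coords), projection) for r in region.interiors]
        geom = Polygon(ext, holes)
    with open(path, "w") as fh:
        json.dump({"type": "Feature", "geometry": mapping(geom), "properties": {}}, fh)


def read_network(edges_path, nodes_path=None,
                 projection: Projection | None = None) -> RoadGraph:
    """Read a road network from GeoJSON LineStrings or a CSV edge list.

    GeoJSON: every LineString becomes a chain of nodes and edges, with node
    identity by exact coordinate.  CSV: ``edges_path`` has columns
    (node_id_a, node_id_b, length_m) and ``nodes_path`` (node_id, lon, lat).
    """
    edges_path = Path(edges_path)
    if edges_path.suffix.lower() in {".geojson", ".json"}:
        with open(edges_path) as fh:
            fc = json.load(fh)
        coords_of: dict = {}
        edges = []
        for feat in fc.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "LineString":
                continue
            pts = geom["coordinates"]
            for a, b in zip(pts[:-1], pts[1:]):
                ka, kb = tuple(a), tuple(b)
                coords_of.setdefault(ka, len(coords_of))
                coords_of.setdefault(kb, len(coords_of))
                edges.append((ka, kb))
        lonlat = np.array(list(coords_of), dtype=float)
        xy = project(lonlat, projection) if projection is not None else lonlat
        node_xy = {coords_of[k]: tuple(xy[i]) for i, k in enumerate(coords_of)}
        edge_list = []
        for ka, kb in edges:
            a, b = coords_of[ka], coords_of[kb]
            pa, pb = np.asarray(node_xy[a]), np.asarray(node_xy[b])
            edge_list.append((a, b, float(np.hypot(*(pa - pb)))))
        return RoadGraph.from_edges(node_xy, edge_list, validate=False)
    if nodes_path is None:
        raise ValueError("CSV edge list requires a node table")
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    ll = nodes[["lon", "lat"]].to_numpy()
    xy = project(ll, projection) if projection is not None else ll
    node_xy = {nid: tuple(p) for nid, p in zip(nodes["node_id"], xy)}
    edge_list = [(a, b, float(l)) for a, b, l in
                 zip(edges["node_id_a"], edges["node_id_b"], edges["length_m"])]
    return RoadGraph.from_edges(node_xy, edge_list)


def write_network_geojson(graph: RoadGraph, path,
                          projection: Projection | None = None) -> None:
    """Write every edge as a two-point LineString FeatureCollection."""
    features = []
    for a, b, data in graph.graph.edges(data=True):
        pa, pb = graph.coords_of(a), graph.coords_of(b)
        coords = np.vstack([pa, pb])
        if projection is not None:
            coords = unproject(coords, projection)
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords.tolist()},
            "properties": {"length_m": data["length"]},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
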