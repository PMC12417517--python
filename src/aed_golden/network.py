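"""Walking-route distances and golden-window walksheds on a road graph.

A :class:`RoadGraph` is an undirected networkx graph whose nodes carry planar
coordinates and whose edges carry lengths in metres.  Off-graph points are
snapped to their nearest node; the straight-line snap offset is added to every
route distance from that point, which bounds the snapping error by twice the
local node spacing.  The walkshed of an origin is the set of road segments
reachable within a time budget at a fixed walking speed (default 3 min at
1.5 m/s, i.e. a 270 m route budget: half the 6-minute golden window before
irreversible brain injury begins without CPR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .geo import as_points

logger = logging.getLogger(__name__)

#: Half-width (m) of the corridor drawn around reachable road segments when a
#: walkshed polygon is built.
WALKSHED_BUFFER_M = 5.0


@dataclass(frozen=True)
class WalkWindow:
    """Walking time budget: ``duration`` seconds at ``speed`` m/s."""

    duration: float = 180.0
    speed: float = 1.5

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.speed <= 0:
            raise ValueError("walk window duration and speed must be positive")

    @property
    def budget(self) -> float:
        """Route-distance budget in metres."""
        return self.duration * self.speed


class RoadGraph:
    """Undirected road network with planar node coordinates and edge lengths."""

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValueError("road graph must contain at least one node")
        self.graph = graph
        self._ids = list(graph.nodes)
        self._coords = np.array([graph.nodes[n]["xy"] for n in self._ids], dtype=float)
        self._tree = cKDTree(self._coords)
        self._index = {n: i for i, n in enumerate(self._ids)}

    @classmethod
    def from_edges(cls, node_coords: dict, edges, validate: bool = True) -> "RoadGraph":
        """Build from ``{node_id: (x, y)}`` and ``(a, b, length_m)`` triples.

        Edge lengths must be positive and at least the straight-line distance
        between their endpoints (within 1e-6 relative tolerance).
        """
        g = nx.Graph()
        for nid, xy in node_coords.items():
            g.add_node(nid, xy=(float(xy[0]), float(xy[1])))
        for a, b, length in edges:
            length = float(length)
            if length <= 0:
                raise ValueError(f"edge ({a}, {b}) has non-positive length {length}")
            if validate:
                pa = np.asarray(node_coords[a], dtype=float)
                pb = np.asarray(node_coords[b], dtype=float)
                euclid = float(np.hypot(*(pa - pb)))
                if length < euclid * (1 - 1e-6):
                    raise ValueError(
                        f"edge ({a}, {b}) length {length:.3f} m is shorter than the "
                        f"straight-line distance {euclid:.3f} m between its endpoints"
                    )
            g.add_edge(a, b, length=length)
        return cls(g)

    @property
    def node_ids(self) -> list:
        return self._ids

    @property
    def node_coords(self) -> np.ndarray:
        return self._coords

    def coords_of(self, node_id) -> np.ndarray:
        return self._coords[self._index[node_id]]

    def largest_component(self) -> "RoadGraph":
        """Restrict to the largest connected component."""
        if nx.is_connected(self.graph):
            return self
        nodes = max(nx.connected_components(self.graph), key=len)
        return RoadGraph(self.graph.subgraph(nodes).copy())

    def snap(self, point) -> tuple[object, float]:
        """Nearest graph node to ``point`` and the straight-line offset to it."""
        pt = as_points(point)[0]
        offset, idx = self._tree.query(pt, k=1)
        return self._ids[int(idx)], float(offset)

    def snap_many(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised :meth:`snap`: (node index array, offset array)."""
        pts = as_points(points)
        offsets, idx = self._tree.query(pts, k=1)
        return np.asarray(idx, dtype=int), np.asarray(offsets, dtype=float)


def route_distance(origins, targets, graph: RoadGraph) -> np.ndarray:
    """Walking-route distance matrix (m) between two planar point sets.

    Each entry is snap-offset(origin) + shortest path + snap-offset(target).
    Disconnected pairs are reported as ``inf`` (and counted in the log), never
    silently dropped; a point coinciding with a node of the path's endpoint
    contributes zero offset.
    """
    o_pts, t_pts = as_points(origins), as_points(targets)
    o_idx, o_off = graph.snap_many(o_pts)
    t_idx, t_off = graph.snap_many(t_pts)
    ids = graph.node_ids
    out = np.full((len(o_pts), len(t_pts)), np.inf)
    # one Dijkstra per distinct origin node
    for node in np.unique(o_idx):
        lengths = nx.single_source_dijkstra_path_length(graph.graph, ids[node], weight="length")
        rows = np.flatnonzero(o_idx == node)
        for j, (tn, toff) in enumerate(zip(t_idx, t_off)):
            d = lengths.get(ids[tn])
            if d is not None:
                out[rows, j] = o_off[rows] + d + toff
    # a point routed to itself through a shared snap node has zero path but
    # double offset; collapse exact coincidences to 0
    same = (o_pts[:, None, :] == t_pts[None, :, :]).all(axis=2)
    out[same & (o_off[:, None] == 0) & (t_off[None, :] == 0)] = 0.0
    n_unreachable = int(np.isinf(out).sum())
    if n_unreachable:
        logger.warning("route_distance: %d origin-target pairs unreachable (reported as inf)",
                       n_unreachable)
    return out


def route_pair_distances(origins, targets, graph: RoadGraph,
                         cutoff=None) -> np.ndarray:
    """Route distance for paired points: one value per (origins[i], targets[i]).

    One Dijkstra per distinct origin snap node, truncated at ``cutoff`` (a
    scalar or a per-pair array) when given.  Pairs that are unreachable (or
    beyond the cutoff) come back as ``inf`` and are counted in the log.
    """
    o_pts, t_pts = as_points(origins), as_points(targets)
    if len(o_pts) != len(t_pts):
        raise ValueError("origins and targets must pair up one-to-one")
    o_idx, o_off = graph.snap_many(o_pts)
    t_idx, t_off = graph.snap_many(t_pts)
    ids = graph.node_ids
    out = np.full(len(o_pts), np.inf)
    cutoffs = None if cutoff is None else np.broadcast_to(
        np.asarray(cutoff, dtype=float), len(o_pts))
    for node in np.unique(o_idx):
        rows = np.flatnonzero(o_idx == node)
        node_cutoff = None if cutoffs is None else float(cutoffs[rows].max())
        lengths = nx.single_source_dijkstra_path_length(
            graph.graph, ids[int(node)], cutoff=node_cutoff, weight="length")
        for i in rows:
            d = lengths.get(ids[int(t_idx[i])])
            if d is not None:
                total = o_off[i] + d + t_off[i]
                if cutoffs is None or total <= cutoffs[i]:
                    out[i] = total
    same = (o_pts == t_pts).all(axis=1) & (o_off == 0) & (t_off == 0)
    out[same] = 0.0
    n_unreachable = int(np.isinf(out).sum())
    if n_unreachable:
        logger.warning("route_pair_distances: %d pairs unreachable (reported as inf)",
                       n_unreachable)
    return out


def reachable_lengths(graph: RoadGraph, origin_node, cutoff: float) -> dict:
    """Shortest-path lengths from ``origin_node`` truncated at ``cutoff`` metres."""
    return nx.single_source_dijkstra_path_length(
        graph.graph, origin_node, cutoff=cutoff, weight="length")


def walkshed(origin, graph: RoadGraph, window: WalkWindow = WalkWindow(),
             buffer_m: float = WALKSHED_BUFFER_M) -> Polygon:
    """Polygon of road space reachable from ``origin`` within the walk window.

    The origin is snapped to its nearest node; the snap offset is spent before
    walking.  Fully and partially reachable edges (with interpolated cut
    points) are buffered by ``buffer_m`` and unioned into a drawable,
    area-computable stand-in for a map-service isochrone.  If the budget does
    not survive the snap offset a degenerate point is returned with a warning.
    """
    pt = as_points(origin)[0]
    node, offset = graph.snap(pt)
    remaining = window.budget - offset
    if remaining <= 0:
        warnings.warn("walk budget exhausted by snap offset; returning a degenerate point")
        return Point(pt).buffer(0)
    dist = reachable_lengths(graph, node, remaining)
    segments = []
    g = graph.graph
    for u, d_u in dist.items():
        pu = graph.coords_of(u)
        for v in g.neighbors(u):
            length = g.edges[u, v]["length"]
            pv = graph.coords_of(v)
            slack = remaining - d_u
            if slack >= length:
                segments.append(LineString([pu, pv]))
            elif slack > 0:
                frac = slack / length
                cut = pu + frac * (pv - pu)
                segments.append(LineString([pu, cut]))
    if not segments:
        return Point(pt).buffer(buffer_m)
    return unary_union([s.buffer(buffer_m) for s in segments])


def route_counts_within(origins, target_points, graph: RoadGraph, cutoff: float,
                        radii=None) -> np.ndarray:
    """Per-origin counts of targets within route distance, at one or many radii.

    For each origin a single-source Dijkstra truncated at ``cutoff`` minus the
    origin's snap offset is run; targets are grouped by their snap node.  When
    ``radii`` is given, returns an (n_origins, n_radii) count matrix for route
    distance <= r; otherwise an (n_origins,) count vector at ``cutoff``.
    """
    o_pts, t_pts = as_points(origins), as_points(target_points)
    o_idx, o_off = graph.snap_many(o_pts)
    t_idx, t_off = graph.snap_many(t_pts)
    ids = graph.node_ids
    by_node: dict[int, list[float]] = {}
    for ti, toff in zip(t_idx, t_off):
        by_node.setdefault(int(ti), []).append(float(toff))
    radii_arr = np.atleast_1d(np.asarray(radii if radii is not None else [cutoff], dtype=float))
    counts = np.zeros((len(o_pts), len(radii_arr)), dtype=int)
    for i, (oi, ooff) in enumerate(zip(o_idx, o_off)):
        budget = cutoff - ooff
        if budget < 0:
            continue
        lengths = reachable_lengths(graph, ids[int(oi)], budget)
        dists = []
        for ti, offs in by_node.items():
            d = lengths.get(ids[ti])
            if d is None:
                continue
            dists.extend(ooff + d + t for t in offs)
        if dists:
            dists = np.sort(np.asarray(dists))
            counts[i] = np.searchsorted(dists, radii_arr, side="right")
    return counts if radii is not None else counts[:, 0]
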