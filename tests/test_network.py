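"""Road-network routing: snapping, shortest paths, walksheds."""

import numpy as np
import pytest

from aed_golden import RoadGraph, WalkWindow, route_distance, walkshed
from aed_golden.network import route_pair_distances, route_counts_within


def grid_graph(n: int = 3, side: float = 100.0) -> RoadGraph:
    """n x n unit-square grid graph with given edge length."""
    nodes = {(i, j): (i * side, j * side) for i in range(n) for j in range(n)}
    edges = []
    for i in range(n):
        for j in range(n):
            if i + 1 < n:
                edges.append(((i, j), (i + 1, j), side))
            if j + 1 < n:
                edges.append(((i, j), (i, j + 1), side))
    return RoadGraph.from_edges(nodes, edges)


def random_connected_graph(rng, n=60, extent=1000.0) -> RoadGraph:
    """Random geometric graph, densified until connected."""
    import networkx as nx
    pts = rng.uniform(0, extent, (n, 2))
    radius = extent / np.sqrt(n)
    while True:
        g = nx.random_geometric_graph(n, radius, pos={i: tuple(p) for i, p in enumerate(pts)})
        if nx.is_connected(g):
            break
        radius *= 1.3
    nodes = {i: tuple(pts[i]) for i in range(n)}
    edges = [(a, b, float(np.hypot(*(pts[a] - pts[b])))) for a, b in g.edges]
    return RoadGraph.from_edges(nodes, edges)


def bellman_ford_oracle(graph: RoadGraph, src, dst) -> float:
    """Independent relaxation-based shortest path (no Dijkstra)."""
    nodes = graph.node_ids
    dist = {n: np.inf for n in nodes}
    dist[src] = 0.0
    edges = [(a, b, d["length"]) for a, b, d in graph.graph.edges(data=True)]
    for _ in range(len(nodes)):
        changed = False
        for a, b, w in edges:
            if dist[a] + w < dist[b]:
                dist[b] = dist[a] + w
                changed = True
            if dist[b] + w < dist[a]:
                dist[a] = dist[b] + w
                changed = True
        if not changed:
            break
    return dist[dst]


class TestGraphValidation:
    def test_edge_shorter_than_euclidean_rejected(self):
        with pytest.raises(ValueError, match="shorter than"):
            RoadGraph.from_edges({0: (0, 0), 1: (100, 0)}, [(0, 1, 50.0)])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            RoadGraph.from_edges({0: (0, 0), 1: (1, 0)}, [(0, 1, 0.0)])

    def test_empty_graph_rejected(self):
        import networkx as nx
        with pytest.raises(ValueError):
            RoadGraph(nx.Graph())


class TestSnap:
    def test_point_on_node_has_zero_offset(self):
        g = grid_graph()
        node, off = g.snap([100.0, 100.0])
        assert node == (1, 1) and off == 0.0

    def test_offset_is_distance_to_nearest_node(self):
        g = grid_graph()
        node, off = g.snap([103.0, 104.0])
        assert node == (1, 1)
        assert off == pytest.approx(5.0)

    def test_matches_brute_force_nearest_node(self, rng):
        g = random_connected_graph(rng, n=80)
        pts = rng.uniform(0, 1000, (100, 2))
        idx, offs = g.snap_many(pts)
        coords = g.node_coords
        for p, i, o in zip(pts, idx, offs):
            d = np.linalg.norm(coords - p, axis=1)
            assert d[i] == pytest.approx(d.min())
            assert o == pytest.approx(d.min())


class TestRouteDistance:
    def test_zero_for_coincident_points_on_node(self):
        g = grid_graph()
        d = route_distance([[100.0, 0.0]], [[100.0, 0.0]], g)
        assert d[0, 0] == 0.0

    def test_grid_corner_to_corner_is_manhattan(self):
        g = grid_graph(3, 100.0)
        d = route_distance([[0.0, 0.0]], [[200.0, 200.0]], g)
        assert d[0, 0] == pytest.approx(400.0)
        straight = np.hypot(200, 200)
        assert straight == pytest.approx(282.8, abs=0.1)
        assert d[0, 0] > straight

    def test_symmetric_on_undirected_graph(self, rng):
        g = random_connected_graph(rng)
        a, b = rng.uniform(0, 1000, (5, 2)), rng.uniform(0, 1000, (5, 2))
        assert np.allclose(route_distance(a, b, g), route_distance(b, a, g).T)

    def test_route_at_least_straight_minus_offsets(self, rng):
        g = random_connected_graph(rng)
        a, b = rng.uniform(0, 1000, (10, 2)), rng.uniform(0, 1000, (10, 2))
        d = route_distance(a, b, g)
        _, ao = g.snap_many(a)
        _, bo = g.snap_many(b)
        straight = np.linalg.norm(a[:, None] - b[None, :], axis=2)
        assert np.all(d >= straight - ao[:, None] - bo[None, :] - 1e-9)

    def test_matches_bellman_ford_oracle(self, rng):
        g = random_connected_graph(rng, n=50)
        coords = g.node_coords
        ids = g.node_ids
        for _ in range(50):
            i, j = rng.integers(0, len(ids), 2)
            d = route_distance([coords[i]], [coords[j]], g)[0, 0]
            assert d == pytest.approx(bellman_ford_oracle(g, ids[i], ids[j]), abs=1e-6)

    def test_disconnected_pair_reported_as_inf(self):
        g = RoadGraph.from_edges({0: (0, 0), 1: (100, 0), 2: (5000, 5000), 3: (5100, 5000)},
                                 [(0, 1, 100.0), (2, 3, 100.0)])
        d = route_distance([[0, 0]], [[5000, 5000]], g)
        assert np.isinf(d[0, 0])

    def test_pair_distances_match_matrix(self, rng):
        g = random_connected_graph(rng)
        a, b = rng.uniform(0, 1000, (8, 2)), rng.uniform(0, 1000, (8, 2))
        pairs = route_pair_distances(a, b, g)
        matrix = route_distance(a, b, g)
        assert np.allclose(pairs, np.diag(matrix))


class TestWalkshed:
    def test_area_bounded_by_budget_disk(self):
        g = grid_graph(9, 50.0)
        window = WalkWindow(duration=180, speed=1.5)  # 270 m budget
        shed = walkshed([200.0, 200.0], g, window)
        assert shed.area <= np.pi * (window.budget + 5.0) ** 2
        assert shed.area > 0

    def test_default_window_budget_is_270m(self):
        assert WalkWindow().budget == pytest.approx(270.0)

    def test_budget_smaller_than_edges_covers_partial_segments_only(self):
        g = grid_graph(3, 100.0)
        shed = walkshed([100.0, 100.0], g, WalkWindow(duration=20, speed=1.5))  # 30 m
        # four 30 m stubs buffered by 5 m, well below one full edge's corridor
        assert shed.area < 4 * (30 + 5) * 10 + np.pi * 25 * 4
        assert shed.bounds[0] >= 100 - 36 and shed.bounds[2] <= 100 + 36

    def test_reachable_nodes_match_weighted_bfs_oracle(self):
        g = grid_graph(7, 100.0)
        budget = 200.0  # two edge lengths
        shed = walkshed([300.0, 300.0], g, WalkWindow(duration=budget / 1.5, speed=1.5))
        # brute-force: BFS with edge weights from the snapped node
        import heapq
        start = (3, 3)
        dist = {start: 0.0}
        heap = [(0.0, start)]
        while heap:
            d, u = heapq.heappop(heap)
            for v in g.graph.neighbors(u):
                nd = d + g.graph.edges[u, v]["length"]
                if nd <= budget and nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        from shapely.geometry import Point
        for node, d in dist.items():
            assert shed.covers(Point(g.coords_of(node)).buffer(-0)) or \
                shed.distance(Point(g.coords_of(node))) < 1e-6
        # nodes strictly beyond budget are outside the corridor interior
        far = Point(g.coords_of((0, 0)))
        assert shed.distance(far) > 5.0

    def test_budget_below_offset_degenerates_with_warning(self):
        g = grid_graph(3, 100.0)
        with pytest.warns(UserWarning, match="budget"):
            shed = walkshed([500.0, 500.0], g, WalkWindow(duration=10, speed=1.5))
        assert shed.area == 0.0

    def test_larger_window_never_shrinks_walkshed(self):
        g = grid_graph(9, 50.0)
        small = walkshed([200.0, 200.0], g, WalkWindow(duration=100, speed=1.5))
        large = walkshed([200.0, 200.0], g, WalkWindow(duration=200, speed=1.5))
        assert large.buffer(1e-6).contains(small)


class TestRouteCounts:
    def test_counts_monotone_in_radius(self, rng):
        g = random_connected_graph(rng)
        ev, dv = rng.uniform(0, 1000, (20, 2)), rng.uniform(0, 1000, (30, 2))
        radii = np.array([100.0, 200.0, 400.0, 800.0])
        counts = route_counts_within(ev, dv, g, cutoff=800.0, radii=radii)
        assert np.all(np.diff(counts, axis=1) >= 0)

    def test_counts_match_pairwise_route_distances(self, rng):
        g = random_connected_graph(rng)
        ev, dv = rng.uniform(0, 1000, (10, 2)), rng.uniform(0, 1000, (15, 2))
        d = route_distance(ev, dv, g)
        counts = route_counts_within(ev, dv, g, cutoff=500.0)
        assert np.array_equal(counts, (d <= 500.0).sum(axis=1))
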