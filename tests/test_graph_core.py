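"""Graph substrate: base-graph construction, MST, distances, I/O."""

import itertools

import numpy as np
import pytest

from physnet.errors import DegenerateGeometryError, DisconnectedGraphError
from physnet.graph_core import (
    City,
    CityMap,
    TransportGraph,
    all_pairs_min_distance_sum,
    build_base_graph,
    is_connected,
    minimum_spanning_tree,
    read_city_map_csv,
    read_edge_list_csv,
    read_graphml,
    write_city_map_csv,
    write_edge_list_csv,
    write_graphml,
)

from conftest import brute_force_mst_length, floyd_warshall_md, random_connected_graph


def make_map(points, **kw):
    cities = [
        City(id=i, name=f"c{i}", x=x, y=y, population=1.0, economic_power=1.0)
        for i, (x, y) in enumerate(points)
    ]
    return CityMap(cities=cities, **kw)


class TestBuildBaseGraph:
    def test_two_cities_complete_pythagorean(self):
        g = build_base_graph(make_map([(0, 0), (3, 4)]), mode="complete")
        assert g.m == 1
        assert g.edges[(0, 1)] == pytest.approx(5.0)

    def test_complete_graph_size(self):
        g = build_base_graph(make_map([(0, 0), (1, 0), (0, 1)]), mode="complete")
        assert g.m == 3

    def test_coincident_cities_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            build_base_graph(make_map([(0, 0), (0, 0), (1, 1)]), mode="complete")

    def test_delaunay_matches_circumcircle_oracle(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 1, size=(10, 2))
        cmap = make_map([tuple(p) for p in pts])
        g = build_base_graph(cmap, mode="delaunay")
        # O(n^4) oracle: a triangle is Delaunay iff its circumcircle is empty
        oracle_edges = set()
        for i, j, k in itertools.combinations(range(10), 3):
            a, b, c = pts[i], pts[j], pts[k]
            d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
            if abs(d) < 1e-12:
                continue
            ux = (
                (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
            ) / d
            uy = (
                (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
            ) / d
            center = np.array([ux, uy])
            r2 = ((a - center) ** 2).sum()
            empty = all(
                ((pts[q] - center) ** 2).sum() >= r2 * (1 - 1e-9)
                for q in range(10)
                if q not in (i, j, k)
            )
            if empty:
                for u, v in [(i, j), (j, k), (i, k)]:
                    oracle_edges.add((min(u, v), max(u, v)))
        assert set(g.edges) == oracle_edges

    def test_delaunay_collinear_falls_back_to_complete(self, caplog):
        cmap = make_map([(0, 0), (1, 0), (2, 0), (3, 0)])
        with caplog.at_level("WARNING"):
            g = build_base_graph(cmap, mode="delaunay")
        assert g.m == 6  # complete on 4 nodes

    def test_delaunay_connected_and_planar_size(self):
        rng = np.random.default_rng(7)
        cmap = make_map([tuple(p) for p in rng.uniform(0, 1, size=(30, 2))])
        g = build_base_graph(cmap, mode="delaunay")
        assert is_connected(g)
        assert g.m <= 3 * 30 - 6  # planarity bound

    def test_knn_disconnected_raises(self):
        # two tight clusters far apart: k=1 links stay within clusters
        pts = [(0, 0), (0, 0.1), (0.1, 0), (10, 10), (10, 10.1), (10.1, 10)]
        with pytest.raises(DisconnectedGraphError):
            build_base_graph(make_map(pts), mode="knn", k=1)


class TestMST:
    def test_tree_is_its_own_mst(self):
        g = TransportGraph(n=4, edges={(0, 1): 1.0, (1, 2): 2.0, (2, 3): 0.5})
        assert minimum_spanning_tree(g).edges == g.edges

    def test_unique_minimum_against_enumeration(self):
        # K4 with lengths 1..6: brute force over all 16 spanning trees
        edges = dict(zip(itertools.combinations(range(4), 2), [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        g = TransportGraph(n=4, edges=edges)
        mst = minimum_spanning_tree(g)
        assert mst.total_length() == pytest.approx(brute_force_mst_length(g))
        assert set(mst.edges) == {(0, 1), (0, 2), (0, 3)}

    @pytest.mark.parametrize("seed", range(5))
    def test_mst_has_n_minus_1_edges(self, seed):
        g = random_connected_graph(np.random.default_rng(seed), 12)
        assert minimum_spanning_tree(g).m == 11

    def test_disconnected_raises_with_components(self):
        g = TransportGraph(n=4, edges={(0, 1): 1.0, (2, 3): 1.0})
        with pytest.raises(DisconnectedGraphError) as err:
            minimum_spanning_tree(g)
        assert err.value.components is not None


class TestMinDistanceSum:
    def test_path_graph_hand_sum(self):
        g = TransportGraph(n=3, edges={(0, 1): 1.0, (1, 2): 1.0})
        assert all_pairs_min_distance_sum(g) == pytest.approx(4.0)

    def test_triangle_hand_sum(self, triangle_graph):
        assert all_pairs_min_distance_sum(triangle_graph) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall_oracle(self, seed):
        g = random_connected_graph(np.random.default_rng(100 + seed), 12)
        assert all_pairs_min_distance_sum(g) == pytest.approx(floyd_warshall_md(g))

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edge_never_increases_md(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = random_connected_graph(rng, 10)
        md = all_pairs_min_distance_sum(g)
        missing = [
            (i, j)
            for i in range(10)
            for j in range(i + 1, 10)
            if (i, j) not in g.edges
        ]
        if not missing:
            pytest.skip("graph already complete")
        extra = missing[int(rng.integers(len(missing)))]
        g2 = TransportGraph(n=10, edges={**g.edges, extra: float(rng.uniform(0.5, 2.0))})
        assert all_pairs_min_distance_sum(g2) <= md + 1e-12


class TestConnectivity:
    def test_single_edge_connected(self):
        assert is_connected(TransportGraph(n=2, edges={(0, 1): 1.0}))

    def test_isolated_node_disconnected(self):
        assert not is_connected(TransportGraph(n=3, edges={(0, 1): 1.0}))

    def test_tree_minus_any_edge_disconnects(self):
        g = TransportGraph(n=4, edges={(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0})
        for e in g.edge_list():
            pruned = dict(g.edges)
            del pruned[e]
            assert not is_connected(TransportGraph(n=4, edges=pruned))


class TestGraphInvariants:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            TransportGraph(n=3, edges={(1, 1): 1.0})

    def test_edges_canonicalized(self):
        g = TransportGraph(n=3, edges={(2, 0): 1.5})
        assert (0, 2) in g.edges


class TestIO:
    def test_city_map_csv_roundtrip(self, tmp_path):
        cmap = make_map([(0.25, -1.5), (3.125, 4.75)])
        path = tmp_path / "cities.csv"
        write_city_map_csv(cmap, path)
        back = read_city_map_csv(path)
        assert [(c.x, c.y) for c in back.cities] == [(c.x, c.y) for c in cmap.cities]

    def test_city_map_json_roundtrip(self, tmp_path):
        from physnet.graph_core import read_city_map_json, write_city_map_json

        cmap = make_map([(0.25, -1.5), (3.125, 4.75)], crs_note="test note")
        path = tmp_path / "cities.json"
        write_city_map_json(cmap, path)
        back = read_city_map_json(path)
        assert back.crs_note == "test note"
        assert back.cities == cmap.cities

    def test_graphml_roundtrip(self, tmp_path):
        g = random_connected_graph(np.random.default_rng(5), 8)
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        assert read_graphml(path).edges == g.edges

    def test_edge_list_csv_roundtrip(self, tmp_path):
        g = random_connected_graph(np.random.default_rng(6), 8)
        path = tmp_path / "edges.csv"
        write_edge_list_csv(g, path)
        assert read_edge_list_csv(path, n=8).edges == g.edges
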