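import itertools

import networkx as nx
import numpy as np
import pytest

from physnet.graph_core import TransportGraph


def random_connected_graph(rng: np.random.Generator, n: int) -> TransportGraph:
    """Seeded random connected graph with lengths uniform in [0.5, 2]."""
    while True:
        p = min(1.0, 2.5 / n + rng.uniform(0.0, 0.3))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(G):
            break
    edges = {(min(u, v), max(u, v)): float(rng.uniform(0.5, 2.0)) for u, v in G.edges}
    return TransportGraph(n=n, edges=edges)


def brute_force_mst_length(g: TransportGraph) -> float:
    """Minimum spanning-tree length by enumerating all (n-1)-edge subsets."""
    best = np.inf
    edges = g.edge_list()
    for subset in itertools.combinations(edges, g.n - 1):
        sub = nx.Graph()
        sub.add_nodes_from(range(g.n))
        sub.add_edges_from(subset)
        if nx.is_connected(sub):
            best = min(best, sum(g.edges[e] for e in subset))
    return best


def floyd_warshall_md(g: TransportGraph) -> float:
    """All-pairs shortest-distance sum via a dense triple loop."""
    n = g.n
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (i, j), length in g.edges.items():
        d[i, j] = d[j, i] = length
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return float(d[np.triu_indices(n, k=1)].sum())


def dijkstra_path_edges(g: TransportGraph, s: int, t: int) -> set[tuple[int, int]]:
    path = nx.dijkstra_path(g.to_networkx(), s, t, weight="length")
    return {(min(a, b), max(a, b)) for a, b in zip(path, path[1:])}


@pytest.fixture
def unit_square_map():
    from physnet.graph_core import City, CityMap

    pts = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    cities = [
        City(id=i, name=f"c{i}", x=x, y=y, population=1e5, economic_power=10.0)
        for i, (x, y) in enumerate(pts)
    ]
    return CityMap(cities=cities, crs_note="test")


@pytest.fixture
def triangle_graph():
    """Unit triangle: source 0, intermediate 1, sink 2."""
    return TransportGraph(n=3, edges={(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})
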