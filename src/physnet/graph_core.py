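"""Spatial problem instances and the graph substrate.

A :class:`CityMap` holds the cities (coordinates, population, economic power)
that define one network-design instance.  A :class:`TransportGraph` is an
undirected weighted graph whose edge weights are physical lengths; the base
graph, the minimum spanning tree and every extracted candidate network share
this shape.

Edges are stored canonically as unordered pairs ``(i, j)`` with ``i < j`` and
0-based node indices.  Lengths are planar Euclidean distances in whatever unit
the coordinates use; no geodesic correction is applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import DegenerateGeometryError, DisconnectedGraphError, PhysnetError

logger = logging.getLogger(__name__)

GraphMode = Literal["delaunay", "complete", "knn"]


@dataclass(frozen=True)
class City:
    """A single urban area: planar position plus gravity-model masses."""

    id: int
    name: str
    x: float
    y: float
    population: float
    economic_power: float

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError(f"city {self.name!r}: population must be > 0")
        if self.economic_power <= 0:
            raise ValueError(f"city {self.name!r}: economic_power must be > 0")


@dataclass
class CityMap:
    """An ordered collection of cities; the spatial problem instance.

    ``crs_note`` records the provenance of the coordinates (real data,
    approximate, or synthetic) so downstream results can be qualified.
    """

    cities: list[City]
    crs_note: str = ""

    def __post_init__(self):
        if len(self.cities) < 2:
            raise ValueError("a CityMap needs at least 2 cities")
        ids = [c.id for c in self.cities]
        if len(set(ids)) != len(ids):
            raise ValueError("city ids must be unique")

    @property
    def n(self) -> int:
        return len(self.cities)

    def coords(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in city order."""
        return np.array([[c.x, c.y] for c in self.cities], dtype=float)

    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.cities], dtype=float)

    def economic_powers(self) -> np.ndarray:
        return np.array([c.economic_power for c in self.cities], dtype=float)

    def pairwise_distances(self) -> np.ndarray:
        xy = self.coords()
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


@dataclass
class TransportGraph:
    """Undirected weighted graph with per-edge physical lengths.

    ``edges`` maps canonical pairs ``(i, j)`` with ``i < j`` to lengths
    ``L_ij > 0``.  The node set is always ``range(n)`` even when some nodes
    are isolated, so connectivity checks stay meaningful after thresholding.
    """

    n: int
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        canon = {}
        for (i, j), length in self.edges.items():
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i},{j}) outside node range 0..{self.n - 1}")
            if length <= 0:
                raise ValueError(f"edge ({i},{j}) has non-positive length {length}")
            key = (i, j) if i < j else (j, i)
            if key in canon and canon[key] != length:
                raise ValueError(f"duplicate edge {key} with conflicting lengths")
            canon[key] = float(length)
        self.edges = canon

    @property
    def m(self) -> int:
        return len(self.edges)

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges in sorted canonical order (deterministic iteration)."""
        return sorted(self.edges)

    def total_length(self) -> float:
        return float(sum(self.edges.values()))

    def length_matrix(self) -> np.ndarray:
        """Symmetric n x n length matrix, 0 where no edge exists."""
        L = np.zeros((self.n, self.n))
        for (i, j), length in self.edges.items():
            L[i, j] = L[j, i] = length
        return L

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for (i, j) in self.edge_list():
            g.add_edge(i, j, length=self.edges[(i, j)])
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, n: int | None = None) -> "TransportGraph":
        n = g.number_of_nodes() if n is None else n
        edges = {(min(i, j), max(i, j)): d["length"] for i, j, d in g.edges(data=True)}
        return cls(n=n, edges=edges)


# ---------------------------------------------------------------------------
# base-graph construction
# ---------------------------------------------------------------------------

def build_base_graph(
    cmap: CityMap, mode: GraphMode = "delaunay", k: int = 4
) -> TransportGraph:
    """Construct the substrate graph the Physarum dynamics run on.

    Modes: ``delaunay`` (planar proximity graph, the default), ``complete``
    (every pair), ``knn`` (each city joined to its ``k`` nearest neighbours,
    symmetrized).  Edge lengths are Euclidean distances between the cities.

    Raises :class:`DegenerateGeometryError` for coincident cities and
    :class:`DisconnectedGraphError` if a knn graph is not connected.  A
    degenerate (collinear) Delaunay input falls back to the complete graph
    with a logged warning.
    """
    dist = cmap.pairwise_distances()
    n = cmap.n
    iu = np.triu_indices(n, k=1)
    if np.any(dist[iu] == 0):
        bad = [(int(i), int(j)) for i, j in zip(*iu) if dist[i, j] == 0]
        raise DegenerateGeometryError(f"coincident cities (zero distance): {bad}")

    if mode == "complete":
        pairs = list(zip(*iu))
    elif mode == "delaunay":
        if n < 3:
            raise ValueError("delaunay mode needs >= 3 cities")
        try:
            tri = Delaunay(cmap.coords())
        except QhullError:
            logger.warning(
                "degenerate (collinear) point set: Delaunay triangulation failed, "
                "falling back to complete graph"
            )
            return build_base_graph(cmap, mode="complete")
        pairs = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                pairs.add((min(i, j), max(i, j)))
        pairs = sorted(pairs)
    elif mode == "knn":
        if not 1 <= k < n:
            raise ValueError(f"knn mode needs 1 <= k < n, got k={k}")
        pairs = set()
        for i in range(n):
            order = np.argsort(dist[i])
            neighbours = [int(j) for j in order if j != i][:k]
            for j in neighbours:
                pairs.add((min(i, j), max(i, j)))
        pairs = sorted(pairs)
    else:
        raise ValueError(f"unknown graph mode {mode!r}")

    g = TransportGraph(n=n, edges={(i, j): float(dist[i, j]) for i, j in pairs})
    if not is_connected(g):
        raise DisconnectedGraphError(
            f"base graph in mode {mode!r} is disconnected; "
            "increase k or use complete mode"
        )
    return g


# ---------------------------------------------------------------------------
# baseline structures and global measures
# ---------------------------------------------------------------------------

def is_connected(g: TransportGraph) -> bool:
    """True iff every node pair is joined by a path (isolated nodes count)."""
    if g.n == 1:
        return True
    return nx.is_connected(g.to_networkx())


def connected_components(g: TransportGraph) -> list[set[int]]:
    return [set(c) for c in nx.connected_components(g.to_networkx())]


def minimum_spanning_tree(g: TransportGraph) -> TransportGraph:
    """Kruskal MST with lexicographic tie-breaking for determinism.

    The MST is the cheapest connected baseline: every evaluation metric is
    normalized against its total length and all-pairs distance sum.
    """
    if not is_connected(g):
        comps = connected_components(g)
        raise DisconnectedGraphError(
            f"MST undefined on disconnected graph with components {comps}",
            components=comps,
        )
    # stable sort on length over canonically sorted edges => lexicographic ties
    nxg = g.to_networkx()
    tree = nx.minimum_spanning_tree(nxg, weight="length", algorithm="kruskal")
    return TransportGraph.from_networkx(tree, n=g.n)


def all_pairs_min_distance_sum(g: TransportGraph) -> float:
    """Sum of shortest-path lengths over all unordered node pairs (MD)."""
    if not is_connected(g):
        raise DisconnectedGraphError("MD undefined: graph is disconnected")
    rows, cols, vals = [], [], []
    for (i, j), length in g.edges.items():
        rows += [i, j]
        cols += [j, i]
        vals += [length, length]
    adj = csr_matrix((vals, (rows, cols)), shape=(g.n, g.n))
    dmat = shortest_path(adj, method="D", directed=False)
    return float(dmat[np.triu_indices(g.n, k=1)].sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CITY_CSV_COLUMNS = ["id", "name", "x", "y", "population", "economic_power"]


def write_city_map_csv(cmap: CityMap, path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": c.id,
                "name": c.name,
                "x": c.x,
                "y": c.y,
                "population": c.population,
                "economic_power": c.economic_power,
            }
            for c in cmap.cities
        ],
        columns=CITY_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_city_map_csv(path, crs_note: str = "") -> CityMap:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CITY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise PhysnetError(f"city CSV missing columns: {sorted(missing)}")
    cities = [
        City(
            id=int(r["id"]),
            name=str(r["name"]),
            x=float(r["x"]),
            y=float(r["y"]),
            population=float(r["population"]),
            economic_power=float(r["economic_power"]),
        )
        for _, r in df.iterrows()
    ]
    return CityMap(cities=cities, crs_note=crs_note)


def write_city_map_json(cmap: CityMap, path) -> None:
    payload = {
        "crs_note": cmap.crs_note,
        "cities": [
            {
                "id": c.id,
                "name": c.name,
                "x": c.x,
                "y": c.y,
                "population": c.population,
                "economic_power": c.economic_power,
            }
            for c in cmap.cities
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_city_map_json(path) -> CityMap:
    with open(path) as fh:
        payload = json.load(fh)
    cities = [City(**row) for row in payload["cities"]]
    return CityMap(cities=cities, crs_note=payload.get("crs_note", ""))


def write_graphml(g: TransportGraph, path) -> None:
    nx.write_graphml(g.to_networkx(), path)


def read_graphml(path) -> TransportGraph:
    nxg = nx.read_graphml(path)
    nxg = nx.relabel_nodes(nxg, {node: int(node) for node in nxg.nodes})
    edges = {
        (min(i, j), max(i, j)): float(d["length"]) for i, j, d in nxg.edges(data=True)
    }
    return TransportGraph(n=nxg.number_of_nodes(), edges=edges)


def write_edge_list_csv(g: TransportGraph, path) -> None:
    df = pd.DataFrame(
        [(i, j, g.edges[(i, j)]) for i, j in g.edge_list()],
        columns=["i", "j", "length"],
    )
    df.to_csv(path, index=False)


def read_edge_list_csv(path, n: int | None = None) -> TransportGraph:
    df = pd.read_csv(path, float_precision="round_trip")
    edges = {
        (min(int(r["i"]), int(r["j"])), max(int(r["i"]), int(r["j"]))): float(
            r["length"]
        )
        for _, r in df.iterrows()
    }
    if n is None:
        n = max(max(i, j) for i, j in edges) + 1
    return TransportGraph(n=n, edges=edges)
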