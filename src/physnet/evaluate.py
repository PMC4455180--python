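"""Candidate-network extraction and evaluation.

A candidate network is cut from the converged conductivity matrix by a
threshold alpha: keep exactly the edges with D_ij >= alpha.  Each connected
candidate is scored by

    TL    total edge length (cost), also reported as TL/TL_MST
    MD    sum of shortest-path distances over all node pairs (performance),
          also reported as MD/MD_MST
    FT    fault tolerance: the fraction of single-link removals that leave
          the network connected (a spanning tree scores 0, a cycle 1)
    efficiency = FT / (TL/TL_MST), the robustness-per-cost trade-off

all normalized against the minimum spanning tree of the base graph.  The
alpha sweep starts at 0.01 and visits the distinct conductivity values (the
only thresholds at which the network changes), recording metrics until the
first disconnection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DisconnectedGraphError, PhysnetError
from .graph_core import (
    TransportGraph,
    all_pairs_min_distance_sum,
    is_connected,
    minimum_spanning_tree,
)

DEFAULT_ALPHA_START = 0.01


@dataclass(frozen=True)
class NetworkMetrics:
    TL: float
    TL_norm: float
    MD: float
    MD_norm: float
    FT: float
    efficiency: float


@dataclass
class AlphaSweepResult:
    """Metrics at each threshold where the network changes, until it breaks."""

    records: list[tuple[float, int, NetworkMetrics]]
    alpha_disconnect: float | None


def extract_network(g: TransportGraph, D, alpha: float) -> TransportGraph:
    """Subgraph keeping exactly the edges with conductivity >= alpha.

    All nodes are retained (possibly isolated), as are original lengths.
    The result may be disconnected or empty; callers check.
    """
    edges = {
        (i, j): length for (i, j), length in g.edges.items() if D[i, j] >= alpha
    }
    return TransportGraph(n=g.n, edges=edges)


def fault_tolerance(g: TransportGraph) -> float:
    """Probability that a random single-link removal leaves the network connected.

    Computed by exhaustive removal of each edge in turn; equals
    1 - (#bridges)/(#edges).  A spanning tree therefore scores 0 and a
    cycle scores 1.
    """
    if g.m == 0:
        raise PhysnetError("fault tolerance undefined on an edgeless graph")
    if not is_connected(g):
        raise DisconnectedGraphError("fault tolerance undefined: graph disconnected")
    survive = 0
    for edge in g.edge_list():
        pruned = dict(g.edges)
        del pruned[edge]
        if is_connected(TransportGraph(n=g.n, edges=pruned)):
            survive += 1
    return survive / g.m


def compute_metrics(network: TransportGraph, mst: TransportGraph) -> NetworkMetrics:
    """Score one candidate network against the MST baseline."""
    if network.n != mst.n:
        raise PhysnetError("network and MST must share a node set")
    if not is_connected(network):
        raise DisconnectedGraphError("metrics undefined on a disconnected network")
    tl = network.total_length()
    tl_mst = mst.total_length()
    md = all_pairs_min_distance_sum(network)
    md_mst = all_pairs_min_distance_sum(mst)
    ft = fault_tolerance(network)
    tl_norm = tl / tl_mst
    return NetworkMetrics(
        TL=tl,
        TL_norm=tl_norm,
        MD=md,
        MD_norm=md / md_mst,
        FT=ft,
        efficiency=ft / tl_norm,
    )


def alpha_sweep(
    g: TransportGraph,
    D,
    alpha_start: float = DEFAULT_ALPHA_START,
    mst: TransportGraph | None = None,
) -> AlphaSweepResult:
    """Record metrics at every threshold where the candidate network changes.

    Thresholds are alpha_start followed by each distinct edge conductivity
    above it, in increasing order; the sweep stops at the first threshold
    whose network is disconnected.
    """
    first = extract_network(g, D, alpha_start)
    if not is_connected(first):
        raise DisconnectedGraphError(
            f"network already disconnected at alpha_start={alpha_start}"
        )
    mst = mst if mst is not None else minimum_spanning_tree(g)
    levels = sorted({float(D[i, j]) for (i, j) in g.edges if D[i, j] > alpha_start})
    records: list[tuple[float, int, NetworkMetrics]] = []
    alpha_disconnect = None
    for alpha in [alpha_start] + levels:
        net = extract_network(g, D, alpha)
        if not is_connected(net):
            alpha_disconnect = alpha
            break
        records.append((alpha, net.m, compute_metrics(net, mst)))
    return AlphaSweepResult(records=records, alpha_disconnect=alpha_disconnect)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SWEEP_COLUMNS = ["alpha", "edges", "TL", "TL_norm", "MD", "MD_norm", "FT", "efficiency"]


def sweep_to_frame(result: AlphaSweepResult) -> pd.DataFrame:
    rows = [
        {
            "alpha": alpha,
            "edges": m,
            "TL": met.TL,
            "TL_norm": met.TL_norm,
            "MD": met.MD,
            "MD_norm": met.MD_norm,
            "FT": met.FT,
            "efficiency": met.efficiency,
        }
        for alpha, m, met in result.records
    ]
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def write_sweep_csv(result: AlphaSweepResult, path) -> None:
    sweep_to_frame(result).to_csv(path, index=False)
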