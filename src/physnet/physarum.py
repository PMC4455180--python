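"""Single origin-sink Physarum current-reinforcement dynamics.

The protoplasmic network is modelled as a resistor network: each tube (edge)
carries an approximately Poiseuille flow

    Q_ij = (D_ij / L_ij) * (p_i - p_j)

with conductivity D_ij and length L_ij.  Kirchhoff balance at every junction
(net flux 0, except +I0 at the source and -I0 at the sink) yields a network
Poisson equation for the node pressures, solved on the grounded
(sink-deleted) weighted Laplacian.  Tube thickness then adapts to use:

    dD_ij/dt = |Q_ij| - gamma * D_ij

discretized by an explicit Euler step.  Under f(Q) = |Q| the conductivities
concentrate on a shortest source-sink path regardless of the initial
distribution, which is what makes the dynamics a path-finding primitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.linalg import spsolve

from .errors import DisconnectedGraphError, PhysnetError, SingularSystemError
from .graph_core import TransportGraph

#: conductivities below this are treated as absent when assembling the
#: pressure system (avoids singular Laplacians); edges are never deleted.
D_FLOOR = 1e-12

DEFAULT_GAMMA = 1.0
DEFAULT_DT = 0.5
DEFAULT_D_INIT = 0.5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_STEPS = 10_000


def _conductance_entries(g: TransportGraph, D: np.ndarray):
    """(i, j, D_ij/L_ij) for conductive edges (D above the floor)."""
    out = []
    for (i, j), length in g.edges.items():
        d = D[i, j]
        if d > D_FLOOR:
            out.append((i, j, d / length))
    return out


def solve_pressures(
    g: TransportGraph,
    D: np.ndarray,
    source: int,
    sink: int,
    I0: float = 1.0,
) -> np.ndarray:
    """Node pressures satisfying Kirchhoff balance, with p_sink = 0.

    Only the conductive subgraph (edges with D above the floor) enters the
    linear system; nodes outside the sink's conductive component carry no
    flux and are assigned pressure 0.  Raises if source and sink fall in
    different conductive components.
    """
    if source == sink:
        raise PhysnetError("source and sink must differ")
    if I0 <= 0:
        raise PhysnetError("I0 must be > 0")
    n = g.n
    entries = _conductance_entries(g, D)
    if not entries:
        raise DisconnectedGraphError("no conductive edges: pressure system empty")

    rows = [e[0] for e in entries] + [e[1] for e in entries]
    cols = [e[1] for e in entries] + [e[0] for e in entries]
    vals = [e[2] for e in entries] * 2
    C = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    ncomp, labels = _cc(C, directed=False)
    if labels[source] != labels[sink]:
        raise DisconnectedGraphError(
            f"source {source} and sink {sink} lie in different conductive components"
        )

    comp_nodes = np.flatnonzero(labels == labels[sink])
    # reduced system over the sink's component with the sink row/col removed
    keep = comp_nodes[comp_nodes != sink]
    pos = {node: idx for idx, node in enumerate(keep)}
    deg = np.asarray(C.sum(axis=1)).ravel()
    lap_rows, lap_cols, lap_vals = [], [], []
    for node in keep:
        lap_rows.append(pos[node])
        lap_cols.append(pos[node])
        lap_vals.append(deg[node])
    for (i, j, c) in entries:
        if i in pos and j in pos:
            lap_rows += [pos[i], pos[j]]
            lap_cols += [pos[j], pos[i]]
            lap_vals += [-c, -c]
    A = coo_matrix((lap_vals, (lap_rows, lap_cols)), shape=(len(keep), len(keep))).tocsr()
    b = np.zeros(len(keep))
    b[pos[source]] = I0

    with np.errstate(all="ignore"):
        x = spsolve(A, b)
    if not np.all(np.isfinite(x)):
        raise SingularSystemError(
            "grounded pressure system is singular "
            f"(component size {len(comp_nodes)}, {len(entries)} conductive edges)"
        )
    p = np.zeros(n)
    p[keep] = x
    return p


def compute_fluxes(g: TransportGraph, D: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Antisymmetric flux matrix Q_ij = (D_ij/L_ij)(p_i - p_j)."""
    n = g.n
    Q = np.zeros((n, n))
    for (i, j), length in g.edges.items():
        d = D[i, j]
        if d > D_FLOOR:
            q = (d / length) * (p[i] - p[j])
            Q[i, j] = q
            Q[j, i] = -q
    return Q


def update_conductivity(
    D: np.ndarray, Q: np.ndarray, gamma: float = DEFAULT_GAMMA, dt: float = DEFAULT_DT
) -> np.ndarray:
    """Explicit Euler step of dD/dt = |Q| - gamma*D, floored at 0."""
    if not 0 < dt <= 1:
        raise ValueError("dt must lie in (0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return np.maximum(D + dt * (np.abs(Q) - gamma * D), 0.0)


def node_imbalance(g: TransportGraph, Q: np.ndarray, source: int, sink: int, I0: float) -> float:
    """Max absolute Kirchhoff residual over nodes (should be ~0 after a solve)."""
    net = Q.sum(axis=1)
    net[source] -= I0
    net[sink] += I0
    return float(np.abs(net).max())


@dataclass
class SingleODResult:
    """Outcome of a single origin-sink relaxation."""

    D: np.ndarray
    converged: bool
    steps: int
    residual: float


def uniform_conductivity(g: TransportGraph, value: float = DEFAULT_D_INIT) -> np.ndarray:
    """Conductivity matrix with the same positive value on every edge."""
    D = np.zeros((g.n, g.n))
    for (i, j) in g.edges:
        D[i, j] = D[j, i] = value
    return D


def run_single_od(
    g: TransportGraph,
    source: int,
    sink: int,
    I0: float = 1.0,
    D_init: np.ndarray | None = None,
    gamma: float = DEFAULT_GAMMA,
    dt: float = DEFAULT_DT,
    max_steps: int = DEFAULT_MAX_STEPS,
    tol: float = DEFAULT_TOL,
) -> SingleODResult:
    """Iterate solve -> flux -> adapt until the conductivities stabilize.

    Stops when the largest per-edge change falls below ``tol * max(D)``.
    At the fixed point the surviving conductivity equals I0/gamma along a
    shortest source-sink path and vanishes elsewhere.
    """
    D = uniform_conductivity(g) if D_init is None else np.array(D_init, dtype=float)
    residual = np.inf
    for step in range(1, max_steps + 1):
        p = solve_pressures(g, D, source, sink, I0)
        Q = compute_fluxes(g, D, p)
        D_new = update_conductivity(D, Q, gamma=gamma, dt=dt)
        residual = float(np.abs(D_new - D).max())
        D = D_new
        if residual < tol * max(D.max(), D_FLOOR):
            return SingleODResult(D=D, converged=True, steps=step, residual=residual)
    return SingleODResult(D=D, converged=False, steps=max_steps, residual=residual)


# ---------------------------------------------------------------------------
# conductivity-matrix I/O
# ---------------------------------------------------------------------------

def write_conductivity_csv(D: np.ndarray, path) -> None:
    n = D.shape[0]
    pd.DataFrame(D, index=range(n), columns=range(n)).to_csv(path)


def read_conductivity_csv(path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float)


def write_conductivity_json(D: np.ndarray, path) -> None:
    triplets = [
        {"i": int(i), "j": int(j), "d": float(D[i, j])}
        for i in range(D.shape[0])
        for j in range(i + 1, D.shape[1])
        if D[i, j] != 0
    ]
    with open(path, "w") as fh:
        json.dump({"n": int(D.shape[0]), "conductivities": triplets}, fh)


def read_conductivity_json(path) -> np.ndarray:
    with open(path) as fh:
        payload = json.load(fh)
    D = np.zeros((payload["n"], payload["n"]))
    for t in payload["conductivities"]:
        D[t["i"], t["j"]] = D[t["j"], t["i"]] = t["d"]
    return D
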