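"""Network design by multi-commodity Physarum relaxation.

Every origin-destination pair with positive gravity demand runs its own
Physarum update (source i, sink j, injection I0 = F_ij) warm-started from
the shared conductivity matrix D_k.  The per-pair matrices are then combined
into D_{k+1} by a demand-weighted convex combination — pairs that move more
traffic have more say in which tubes survive — and rescaled so the largest
conductivity is 1.  Feeding D_{k+1} forward couples the commodities: edges
serving many heavy flows reinforce, links used by nobody decay and
disappear.  The outer loop stops when successive conductivity matrices
differ by less than delta everywhere (delta = 0.01 by default).

Pairs are processed against the same frozen D_k within a sweep (Jacobi
style), so the result is independent of pair ordering and bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DisconnectedGraphError, PhysnetError
from .gravity import normalize_flows
from .graph_core import TransportGraph, is_connected
from .physarum import (
    DEFAULT_DT,
    DEFAULT_GAMMA,
    compute_fluxes,
    solve_pressures,
    uniform_conductivity,
    update_conductivity,
)

logger = logging.getLogger(__name__)

Aggregation = Literal["flow_weighted", "uniform"]


@dataclass(frozen=True)
class DesignConfig:
    """Knobs of the outer design loop.

    delta        convergence threshold on the max elementwise change of the
                 normalized conductivity matrix between sweeps (0.01).
    inner_steps  Physarum iterations each O-D pair runs per sweep (1).
    max_outer    cap on outer sweeps before giving up.
    aggregation  'flow_weighted' (demand-weighted convex combination) or
                 'uniform' (plain average; ablation mode).
    normalize_demand  max-normalize F before use so per-pair injections and
                 conductivities share the [0, 1] scale.
    d_init       initial per-edge conductivity; a float for a uniform start
                 or 'random' for a seeded uniform(0,1) draw per edge.
    """

    delta: float = 0.01
    inner_steps: int = 1
    max_outer: int = 200
    aggregation: Aggregation = "flow_weighted"
    seed: int = 0
    gamma: float = DEFAULT_GAMMA
    dt: float = DEFAULT_DT
    d_init: float | str = 0.5
    normalize_demand: bool = True

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.inner_steps < 1:
            raise ValueError("inner_steps must be >= 1")


@dataclass
class DesignResult:
    """Converged (or truncated) outcome of the outer loop."""

    D_final: np.ndarray
    outer_iterations: int
    converged: bool
    history: list[float] = field(default_factory=list)


def positive_pairs(F: np.ndarray) -> list[tuple[int, int]]:
    """Unordered O-D pairs with positive demand, in canonical order."""
    n = F.shape[0]
    return [(i, j) for i in range(n) for j in range(i + 1, n) if F[i, j] > 0]


def od_sweep(
    g: TransportGraph,
    F: np.ndarray,
    D_k: np.ndarray,
    inner_steps: int = 1,
    gamma: float = DEFAULT_GAMMA,
    dt: float = DEFAULT_DT,
) -> dict[tuple[int, int], np.ndarray]:
    """One Jacobi sweep: every positive-demand pair updates its own copy of D_k.

    Returns the per-pair conductivity matrices D_k^(ij).  Zero-demand pairs
    are skipped entirely; self-pairs are degenerate and never enter.
    """
    pairs = positive_pairs(F)
    if not pairs:
        raise PhysnetError("flow matrix has no positive off-diagonal entry")
    out: dict[tuple[int, int], np.ndarray] = {}
    for (i, j) in pairs:
        D = np.array(D_k, dtype=float)
        try:
            for _ in range(inner_steps):
                p = solve_pressures(g, D, source=i, sink=j, I0=float(F[i, j]))
                Q = compute_fluxes(g, D, p)
                D = update_conductivity(D, Q, gamma=gamma, dt=dt)
        except DisconnectedGraphError as exc:
            raise DisconnectedGraphError(
                f"O-D pair ({i}, {j}) disconnected in the conductive subgraph: {exc}"
            ) from exc
        out[(i, j)] = D
    return out


def aggregate_conductivities(
    mats: dict[tuple[int, int], np.ndarray],
    F: np.ndarray,
    mode: Aggregation = "flow_weighted",
) -> np.ndarray:
    """Combine per-pair matrices into one network-wide conductivity.

    'flow_weighted' weighs each pair by its share of total demand, so the
    role a pair plays in the network is proportional to the traffic it
    carries; 'uniform' averages all pairs equally.
    """
    if not mats:
        raise PhysnetError("cannot aggregate an empty list of conductivity matrices")
    pairs = sorted(mats)
    if mode == "flow_weighted":
        weights = np.array([F[i, j] for i, j in pairs], dtype=float)
        total = weights.sum()
        if total <= 0:
            raise PhysnetError("flow weights sum to zero")
        weights = weights / total
    elif mode == "uniform":
        weights = np.full(len(pairs), 1.0 / len(pairs))
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    out = np.zeros_like(next(iter(mats.values())))
    for w, pair in zip(weights, pairs):
        out += w * mats[pair]
    return out


def normalize_conductivity(D: np.ndarray) -> np.ndarray:
    """Rescale so max(D) = 1, keeping every entry in [0, 1]."""
    peak = D.max()
    if peak <= 0:
        raise PhysnetError("conductivity matrix vanished: nothing left to normalize")
    return D / peak


def initial_conductivity(g: TransportGraph, cfg: DesignConfig) -> np.ndarray:
    if cfg.d_init == "random":
        rng = np.random.default_rng(cfg.seed)
        D = np.zeros((g.n, g.n))
        for (i, j) in g.edge_list():
            D[i, j] = D[j, i] = rng.uniform(0.05, 1.0)
        return D
    return uniform_conductivity(g, float(cfg.d_init))


def run_design(
    g: TransportGraph, F: np.ndarray, cfg: DesignConfig | None = None
) -> DesignResult:
    """Outer loop: sweep -> aggregate -> normalize until D stabilizes.

    Returns the normalized conductivity matrix (max exactly 1), the number
    of sweeps, a convergence flag, and the per-sweep max elementwise change.
    """
    cfg = cfg or DesignConfig()
    if not is_connected(g):
        raise DisconnectedGraphError("design requires a connected base graph")
    F = np.asarray(F, dtype=float)
    if F.shape != (g.n, g.n):
        raise PhysnetError(f"flow matrix shape {F.shape} does not match n={g.n}")
    Fd = normalize_flows(F, "max") if cfg.normalize_demand else F

    D = initial_conductivity(g, cfg)
    history: list[float] = []
    for k in range(1, cfg.max_outer + 1):
        mats = od_sweep(
            g, Fd, D, inner_steps=cfg.inner_steps, gamma=cfg.gamma, dt=cfg.dt
        )
        D_next = normalize_conductivity(
            aggregate_conductivities(mats, Fd, cfg.aggregation)
        )
        change = float(np.abs(D_next - D).max())
        history.append(change)
        D = D_next
        if change < cfg.delta:
            logger.info("design loop converged after %d sweeps (change %.3g)", k, change)
            return DesignResult(D_final=D, outer_iterations=k, converged=True, history=history)
    logger.warning(
        "design loop hit max_outer=%d without stabilizing (last change %.3g)",
        cfg.max_outer,
        history[-1] if history else float("nan"),
    )
    return DesignResult(
        D_final=D, outer_iterations=cfg.max_outer, converged=False, history=history
    )
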