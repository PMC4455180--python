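"""Gravity-model trip distribution.

Inter-city travel demand is estimated as

    F_ij = G * M_i^a1 * M_j^a2 / D_ij^a3

where the masses M are city attributes and D_ij is the inter-city distance.
The default configuration uses GDP (economic power) as mass with
a1 = a2 = 0.5 and a3 = 0: demand is the square root of the product of the
two GDPs and does not depend on distance at all.  The classical
population-based variant sqrt(P_i * P_j) / D_ij^2 is provided for comparison.

All matrices are symmetric (a1 = a2 by default) with a zero diagonal; a
city's total traffic volume is the row sum of F (its outward flow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, PhysnetError
from .graph_core import CityMap


@dataclass(frozen=True)
class GravityParams:
    """Gravity-model constants: overall scale G and the three exponents."""

    scale: float = 1.0
    alpha1: float = 0.5
    alpha2: float = 0.5
    alpha3: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def combine_economic_power(values: Iterable[float]) -> float:
    """Single mass for a table row that lists several cities.

    A row enumerating more than one urban area contributes one node whose
    economic power is the sum of the listed powers (e.g. powers 2, 1, 7
    combine to 10).
    """
    values = list(values)
    if not values:
        raise PhysnetError("cannot combine an empty list of economic powers")
    return float(sum(values))


def _gravity_matrix(
    masses: np.ndarray, dist: np.ndarray, params: GravityParams
) -> np.ndarray:
    n = len(masses)
    F = params.scale * np.outer(
        masses**params.alpha1, masses**params.alpha2
    )
    if params.alpha3 != 0:
        off = ~np.eye(n, dtype=bool)
        if np.any(dist[off] == 0):
            raise DegenerateGeometryError(
                "alpha3 > 0 with coincident cities: division by zero distance"
            )
        with np.errstate(divide="ignore"):
            denom = dist**params.alpha3
        F = np.where(off, F / np.where(denom == 0, 1.0, denom), F)
    np.fill_diagonal(F, 0.0)
    return F


def estimate_flows(cmap: CityMap, params: GravityParams | None = None) -> np.ndarray:
    """O-D demand matrix from economic power (GDP) masses.

    With the default exponents the result is symmetric, has zero diagonal,
    and is independent of the city coordinates.
    """
    params = params or GravityParams()
    masses = cmap.economic_powers()
    if np.any(masses <= 0):
        raise PhysnetError("all economic powers must be > 0")
    return _gravity_matrix(masses, cmap.pairwise_distances(), params)


def classical_flows(cmap: CityMap, params: GravityParams | None = None) -> np.ndarray:
    """Classical population/distance-squared gravity demand.

    F_ij = scale * sqrt(P_i * P_j) / D_ij^2.  Requires distinct coordinates.
    """
    params = params or GravityParams(alpha3=2.0)
    return _gravity_matrix(cmap.populations(), cmap.pairwise_distances(), params)


def outbound_flow(F: np.ndarray) -> np.ndarray:
    """Per-city total traffic volume: the row sum of the demand matrix."""
    return np.asarray(F).sum(axis=1)


def normalize_flows(F: np.ndarray, mode: Literal["max", "sum"] = "max") -> np.ndarray:
    """Rescale demand: 'max' puts the largest entry at 1 (the scale the
    conductivity matrix lives on); 'sum' makes entries a distribution."""
    F = np.asarray(F, dtype=float)
    if mode == "max":
        denom = F.max()
    elif mode == "sum":
        denom = F.sum()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise PhysnetError("cannot normalize an all-zero flow matrix")
    return F / denom


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_flow_csv(F: np.ndarray, path, ids: list[int] | None = None) -> None:
    n = F.shape[0]
    ids = ids if ids is not None else list(range(n))
    pd.DataFrame(F, index=ids, columns=ids).to_csv(path)


def read_flow_csv(path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float)


def write_flow_json(F: np.ndarray, path) -> None:
    triplets = [
        {"i": int(i), "j": int(j), "flow": float(F[i, j])}
        for i in range(F.shape[0])
        for j in range(i + 1, F.shape[1])
        if F[i, j] != 0
    ]
    with open(path, "w") as fh:
        json.dump({"n": int(F.shape[0]), "flows": triplets}, fh)


def read_flow_json(path) -> np.ndarray:
    with open(path) as fh:
        payload = json.load(fh)
    F = np.zeros((payload["n"], payload["n"]))
    for t in payload["flows"]:
        F[t["i"], t["j"]] = F[t["j"], t["i"]] = t["flow"]
    return F
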