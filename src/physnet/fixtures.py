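"""Self-contained test and demonstration inputs.

Two kinds of input live here: a seeded generator of synthetic city maps with
the statistical structure the gravity model assumes (heavy-tailed
populations, GDP tightly coupled to population), and packaged encodings of
two published city tables — 19 Mexican urban areas (population plus a
rank-style economic-power score) and 31 Chinese urban areas (population,
GDP and observed traffic volume).

The published tables carry no coordinates; the bundled x/y values are
approximate city longitudes/latitudes added here for geometry-dependent
code paths, and every map built from them says so in its ``crs_note``.
Table rows that enumerate several urban areas (Mexico rows 14 and 19)
collapse to a single node whose economic power is the sum of the listed
powers and whose population is the sum of the listed populations.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PhysnetError
from .gravity import combine_economic_power
from .graph_core import City, CityMap


def _data_path(name: str):
    return resources.files("physnet").joinpath("data", name)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a seeded random city map.

    Cities are placed uniformly in an axis-aligned box with a minimum
    pairwise separation (rejection sampling).  Populations are drawn from a
    heavy-tailed distribution and GDP follows a noisy power law
    GDP = c * population**beta * lognormal(sigma), mirroring the strong
    empirical GDP-population coupling of real city systems.
    """

    n_cities: int = 10
    seed: int = 0
    region: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)
    population_dist: str = "lognormal"  # or "powerlaw"
    population_median: float = 5.0e5
    population_sigma: float = 0.75
    powerlaw_alpha: float = 2.0
    gdp_scale: float = 1.0e-4
    gdp_beta: float = 1.0
    gdp_noise_sigma: float = 0.3
    min_separation: float | None = None  # default 0.3/sqrt(n) of box diagonal scale

    def __post_init__(self):
        if self.n_cities < 2:
            raise ValueError("need at least 2 cities")
        x0, y0, x1, y1 = self.region
        if x1 <= x0 or y1 <= y0:
            raise ValueError("region box must have positive extent")


def generate_city_map(spec: SyntheticSpec) -> CityMap:
    """Seed-deterministic synthetic city map satisfying all CityMap invariants."""
    rng = np.random.default_rng(spec.seed)
    x0, y0, x1, y1 = spec.region
    scale = min(x1 - x0, y1 - y0)
    sep = (
        spec.min_separation
        if spec.min_separation is not None
        else 0.3 * scale / np.sqrt(spec.n_cities)
    )
    points: list[tuple[float, float]] = []
    attempts = 0
    while len(points) < spec.n_cities:
        attempts += 1
        if attempts > 10_000 * spec.n_cities:
            raise PhysnetError(
                f"region too small for {spec.n_cities} cities at min separation {sep:g}"
            )
        x = rng.uniform(x0, x1)
        y = rng.uniform(y0, y1)
        if all((x - px) ** 2 + (y - py) ** 2 >= sep**2 for px, py in points):
            points.append((x, y))

    if spec.population_dist == "lognormal":
        pops = spec.population_median * rng.lognormal(
            0.0, spec.population_sigma, spec.n_cities
        )
    elif spec.population_dist == "powerlaw":
        # Pareto with minimum population_median and tail index powerlaw_alpha
        pops = spec.population_median * (
            1.0 + rng.pareto(spec.powerlaw_alpha, spec.n_cities)
        )
    else:
        raise ValueError(f"unknown population_dist {spec.population_dist!r}")
    gdps = (
        spec.gdp_scale
        * pops**spec.gdp_beta
        * rng.lognormal(0.0, spec.gdp_noise_sigma, spec.n_cities)
    )
    cities = [
        City(
            id=i,
            name=f"city{i}",
            x=float(points[i][0]),
            y=float(points[i][1]),
            population=float(pops[i]),
            economic_power=float(gdps[i]),
        )
        for i in range(spec.n_cities)
    ]
    return CityMap(cities=cities, crs_note=f"synthetic (seed={spec.seed})")


# ---------------------------------------------------------------------------
# packaged city tables
# ---------------------------------------------------------------------------

def mexico_table() -> list[dict]:
    """Raw rows of the Mexico table, multi-city rows left uncombined."""
    with _data_path("mexico_table.json").open() as fh:
        return json.load(fh)["rows"]


def mexico_fixture() -> CityMap:
    """19 Mexican urban areas with rank-style economic power scores.

    Rows listing several urban areas become a single node with summed
    populations and summed economic powers.
    """
    rows = mexico_table()
    cities = [
        City(
            id=idx,
            name=row["name"],
            x=row["x"],
            y=row["y"],
            population=float(sum(row["populations"])),
            economic_power=combine_economic_power(row["economic_powers"]),
        )
        for idx, row in enumerate(rows)
    ]
    return CityMap(
        cities=cities,
        crs_note="synthetic - approximate lon/lat, not from the source table",
    )


def china_table() -> pd.DataFrame:
    """Raw China table: population, GDP (1e9 RMB) and observed traffic (1e4)."""
    with _data_path("china_table.csv").open() as fh:
        return pd.read_csv(fh)


def china_fixture() -> CityMap:
    """31 Chinese urban areas with GDP as economic power."""
    df = china_table()
    cities = [
        City(
            id=int(r["id"]),
            name=str(r["name"]),
            x=float(r["x"]),
            y=float(r["y"]),
            population=float(r["population"]),
            economic_power=float(r["gdp"]),
        )
        for _, r in df.iterrows()
    ]
    return CityMap(
        cities=cities,
        crs_note="synthetic - approximate lon/lat, not from the source table",
    )


def china_actual_flows() -> pd.DataFrame:
    """Observed per-city traffic volumes, for ranking comparisons only."""
    return china_table()[["id", "name", "actual_traffic_flow"]]
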