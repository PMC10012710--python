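"""Synthetic city generator: road network, population grid and facility catalog.

Produces inputs with the statistical structure that the accessibility
analysis assumes for a congested African city: a connected road network
whose peak-hour traversal times are never faster than free flow and whose
congestion concentrates toward the city centre; a fine-resolution (100 m)
population grid that is populated everywhere, peripheries included; and a
facility catalog that is strongly centre-biased, split into primary,
secondary and tertiary care tiers with tier-average staffing.

All randomness flows from a single root seed, so every generated city is
reproducible byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Tier",
    "Rect",
    "CityConfig",
    "StaffingProfile",
    "Facility",
    "PopulationGrid",
    "RoadNetwork",
    "default_staffing",
    "generate_city",
    "DEFAULT_FACILITY_COUNTS",
]


class Tier(str, Enum):
    """Facility care level: dispensaries/clinics/health centres (primary),
    sub-county/county and medium-large private hospitals (secondary),
    national referral hospitals (tertiary)."""

    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"

    @classmethod
    def coerce(cls, value: "Tier | str") -> "Tier":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown facility tier {value!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in planar meters."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("rectangle must have positive width and height")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax


#: Nairobi-like tier split: 1,042 facilities, ~91% primary, ~9% secondary, ~1% tertiary.
DEFAULT_FACILITY_COUNTS: dict[Tier, int] = {
    Tier.PRIMARY: 944,
    Tier.SECONDARY: 94,
    Tier.TERTIARY: 4,
}

#: Tier-average staffing (nurses/midwives, clinical officers, doctors) per
#: facility, from national service-provision survey averages. Primary
#: facilities report no doctors, encoded as 0.
_TIER_STAFFING: dict[Tier, tuple[int, int, int]] = {
    Tier.PRIMARY: (8, 3, 0),
    Tier.SECONDARY: (13, 4, 2),
    Tier.TERTIARY: (288, 30, 10),
}


@dataclass(frozen=True)
class StaffingProfile:
    """Healthcare professionals at one facility (HP in the staff ratio)."""

    nurses_midwives: int
    clinical_officers: int
    doctors: int

    def __post_init__(self) -> None:
        for name in ("nurses_midwives", "clinical_officers", "doctors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def total(self) -> int:
        return self.nurses_midwives + self.clinical_officers + self.doctors


def default_staffing(tier: Tier | str) -> StaffingProfile:
    """Tier-average staffing profile for a facility of the given tier."""
    tier = Tier.coerce(tier)
    return StaffingProfile(*_TIER_STAFFING[tier])


@dataclass(frozen=True)
class Facility:
    """A supply point: one facility unit (F = 1) plus its staff (HP)."""

    facility_id: str
    x: float
    y: float
    tier: Tier
    staffing: StaffingProfile

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class CityConfig:
    """Parameters of the synthetic city.

    The defaults describe a Nairobi-scale rectangle: a ~30 km x 25 km
    extent, 4.4 million residents, 1,042 facilities split 944/94/4 across
    tiers, and peak-hour congestion that can double or triple free-flow
    travel times near the centre.
    """

    extent: Rect = Rect(0.0, 0.0, 30_000.0, 25_000.0)
    cell_size: float = 100.0
    total_population: int = 4_400_000
    n_facilities_by_tier: Mapping[Tier, int] = field(
        default_factory=lambda: dict(DEFAULT_FACILITY_COUNTS)
    )
    facility_centrality: float = 2.0
    peak_multiplier_range: tuple[float, float] = (1.3, 3.0)
    road_grid_spacing: float = 500.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.total_population < 0:
            raise ValueError("total_population must be >= 0")
        if self.road_grid_spacing <= 0:
            raise ValueError("road_grid_spacing must be > 0")
        if self.facility_centrality < 0:
            raise ValueError("facility_centrality must be >= 0")
        counts = {Tier.coerce(t): int(n) for t, n in self.n_facilities_by_tier.items()}
        if any(n < 0 for n in counts.values()):
            raise ValueError("facility counts must be >= 0")
        object.__setattr__(self, "n_facilities_by_tier", counts)
        lo, hi = self.peak_multiplier_range
        if lo < 1.0 or hi < lo:
            raise ValueError(
                "peak_multiplier_range must satisfy 1 <= lower <= upper "
                "(peak is never faster than off-peak)"
            )


@dataclass
class PopulationGrid:
    """Regular lattice of square cells holding the population that demands care.

    ``cell_ids``, ``x``, ``y`` and ``population`` are parallel arrays; x/y
    are cell centroids in meters.
    """

    cell_ids: np.ndarray  # str array
    x: np.ndarray
    y: np.ndarray
    population: np.ndarray
    cell_size: float
    extent: Rect

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if not (len(self.x) == len(self.y) == len(self.population) == n):
            raise ValueError("grid arrays must be parallel")
        pop = np.asarray(self.population, dtype=float)
        if not np.all(np.isfinite(pop)) or np.any(pop < 0):
            raise ValueError("cell populations must be finite and >= 0")
        self.population = pop

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def total_population(self) -> float:
        return float(self.population.sum())

    def subset(self, mask: np.ndarray) -> "PopulationGrid":
        return PopulationGrid(
            cell_ids=self.cell_ids[mask],
            x=self.x[mask],
            y=self.y[mask],
            population=self.population[mask],
            cell_size=self.cell_size,
            extent=self.extent,
        )

    def population_of(self) -> dict[str, float]:
        return dict(zip(self.cell_ids.tolist(), self.population.tolist()))


@dataclass
class RoadNetwork:
    """Undirected road graph with scenario-dependent traversal times.

    Node attributes: ``x``, ``y`` (meters). Edge attributes: ``length``
    (m), ``free_flow_speed`` (m/min) and ``peak_multiplier`` (>= 1).
    Off-peak traversal time is length / free_flow_speed; peak time is the
    off-peak time scaled by the edge's congestion multiplier.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if d["length"] < 0 or d["free_flow_speed"] <= 0:
                raise ValueError(f"invalid edge geometry on ({u}, {v})")
            if d["peak_multiplier"] < 1.0:
                raise ValueError(
                    f"peak_multiplier < 1 on edge ({u}, {v}): peak cannot "
                    "be faster than off-peak"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def node_coordinates(self) -> tuple[list, np.ndarray]:
        """Node ids and an (n, 2) coordinate array, in graph order."""
        nodes = list(self.graph.nodes)
        xy = np.array(
            [[self.graph.nodes[n]["x"], self.graph.nodes[n]["y"]] for n in nodes]
        )
        return nodes, xy

    def edge_time(self, u, v, scenario: str) -> float:
        d = self.graph.edges[u, v]
        t = d["length"] / d["free_flow_speed"]
        if scenario == "peak":
            t *= d["peak_multiplier"]
        return t

    def largest_component_fraction(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        biggest = max(nx.connected_components(self.graph), key=len)
        return len(biggest) / self.n_nodes


# ---------------------------------------------------------------------------
# generation


def _generate_network(config: CityConfig, rng: np.random.Generator) -> RoadNetwork:
    ext = config.extent
    s = config.road_grid_spacing
    nx_pts = int(ext.width // s) + 1
    ny_pts = int(ext.height // s) + 1
    if nx_pts < 2 or ny_pts < 2:
        raise ValueError(
            f"extent {ext.width:.0f} x {ext.height:.0f} m too small for a road "
            f"lattice with spacing {s:.0f} m"
        )
    cx, cy = ext.center
    half_diag = math.hypot(ext.width, ext.height) / 2.0
    # perturbed lattice: jitter node coordinates by up to 20% of spacing
    jitter = rng.uniform(-0.2 * s, 0.2 * s, size=(ny_pts, nx_pts, 2))
    g = nx.Graph()
    coords = {}
    for j in range(ny_pts):
        for i in range(nx_pts):
            x = min(max(ext.xmin + i * s + jitter[j, i, 0], ext.xmin), ext.xmax)
            y = min(max(ext.ymin + j * s + jitter[j, i, 1], ext.ymin), ext.ymax)
            node = f"n{j}_{i}"
            g.add_node(node, x=float(x), y=float(y))
            coords[node] = (x, y)
    lo, hi = config.peak_multiplier_range
    for j in range(ny_pts):
        for i in range(nx_pts):
            u = f"n{j}_{i}"
            for dj, di in ((0, 1), (1, 0)):
                jj, ii = j + dj, i + di
                if jj >= ny_pts or ii >= nx_pts:
                    continue
                v = f"n{jj}_{ii}"
                ux, uy = coords[u]
                vx, vy = coords[v]
                length = math.hypot(vx - ux, vy - uy)
                speed = rng.uniform(300.0, 700.0)  # m/min (~18-42 km/h free flow)
                base = rng.uniform(lo, hi)
                # congestion concentrates centrally: the drawn multiplier is
                # attenuated toward 1 with distance from the centre
                mx, my = (ux + vx) / 2.0, (uy + vy) / 2.0
                closeness = 1.0 - math.hypot(mx - cx, my - cy) / half_diag
                mult = 1.0 + (base - 1.0) * (0.25 + 0.75 * max(closeness, 0.0))
                g.add_edge(
                    u,
                    v,
                    length=float(length),
                    free_flow_speed=float(speed),
                    peak_multiplier=float(mult),
                )
    return RoadNetwork(g)


def _generate_facilities(
    config: CityConfig, rng: np.random.Generator
) -> list[Facility]:
    ext = config.extent
    cx, cy = ext.center
    facilities: list[Facility] = []
    k = 0
    for tier in (Tier.PRIMARY, Tier.SECONDARY, Tier.TERTIARY):
        n = config.n_facilities_by_tier.get(tier, 0)
        for _ in range(n):
            # uniform point contracted toward the centre: contraction factor
            # u**centrality is Beta-distributed, so centrality 0 is uniform
            # and larger values pull density into the core
            ux = rng.uniform(ext.xmin, ext.xmax)
            uy = rng.uniform(ext.ymin, ext.ymax)
            beta = rng.uniform() ** config.facility_centrality
            x = cx + (ux - cx) * beta
            y = cy + (uy - cy) * beta
            facilities.append(
                Facility(
                    facility_id=f"f{k:04d}",
                    x=float(x),
                    y=float(y),
                    tier=tier,
                    staffing=default_staffing(tier),
                )
            )
            k += 1
    return facilities


def _generate_grid(config: CityConfig, rng: np.random.Generator) -> PopulationGrid:
    ext = config.extent
    cs = config.cell_size
    ncols = max(int(ext.width // cs), 1)
    nrows = max(int(ext.height // cs), 1)
    xs = ext.xmin + cs * (np.arange(ncols) + 0.5)
    ys = ext.ymin + cs * (np.arange(nrows) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    cell_ids = np.array(
        [f"c{r}_{c}" for r in range(nrows) for c in range(ncols)], dtype=object
    )
    n = len(gx)
    # heavy-tailed (log-normal) heterogeneity with a mild centre gradient;
    # peripheries stay populated, as in the real city
    cx, cy = ext.center
    half_diag = math.hypot(ext.width, ext.height) / 2.0
    d = np.hypot(gx - cx, gy - cy) / half_diag
    weights = rng.lognormal(mean=0.0, sigma=0.8, size=n) * (0.5 + np.exp(-2.0 * d))
    weights /= weights.sum()
    population = rng.multinomial(config.total_population, weights).astype(float)
    return PopulationGrid(
        cell_ids=cell_ids,
        x=gx.astype(float),
        y=gy.astype(float),
        population=population,
        cell_size=cs,
        extent=ext,
    )


def generate_city(
    config: CityConfig,
) -> tuple[RoadNetwork, PopulationGrid, list[Facility]]:
    """Generate a synthetic city from a validated configuration.

    Deterministic given ``config.rng_seed``: the network, grid and facility
    stages each consume an independent child stream of one root RNG, so a
    stage can be regenerated without disturbing the others.
    """
    root = np.random.SeedSequence(config.rng_seed)
    net_rng, fac_rng, grid_rng = (np.random.default_rng(s) for s in root.spawn(3))
    network = _generate_network(config, net_rng)
    facilities = _generate_facilities(config, fac_rng)
    grid = _generate_grid(config, grid_rng)
    return network, grid, facilities


def demo_config(seed: int = 0) -> CityConfig:
    """A small city (20 x 20 cells, 12 facilities) that runs in seconds."""
    return CityConfig(
        extent=Rect(0.0, 0.0, 2_000.0, 2_000.0),
        cell_size=100.0,
        total_population=50_000,
        n_facilities_by_tier={Tier.PRIMARY: 8, Tier.SECONDARY: 3, Tier.TERTIARY: 1},
        facility_centrality=1.5,
        peak_multiplier_range=(1.3, 3.0),
        road_grid_spacing=400.0,
        rng_seed=seed,
    )
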