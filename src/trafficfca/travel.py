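"""Scenario-dependent travel times and drive-time catchments.

Travel time from a facility to a population cell is computed in three
legs: a walking leg from the facility to its nearest road node, a driving
leg along the network under the scenario's edge costs (shortest path), and
a walking leg from the cell's nearest road node to the cell centroid. The
network is undirected, so facility-to-population and population-to-facility
times coincide.

A catchment at threshold ``tt0`` is the set of cells whose total time is
at most ``tt0`` (inclusive), together with their summed population — the
demand denominator of the floating-catchment ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .synthetic_city import Facility, PopulationGrid, RoadNetwork

__all__ = [
    "Scenario",
    "WALK_SPEED",
    "MAX_SNAP",
    "DEFAULT_THRESHOLDS",
    "TravelTimeField",
    "Catchment",
    "snap_to_network",
    "NetworkRouter",
    "travel_time_field",
    "travel_time_fields",
    "build_catchment",
]

#: Walking speed for the off-network access legs, m/min (4.8 km/h).
WALK_SPEED = 80.0
#: Points farther than this from every road node are treated as off-network.
MAX_SNAP = 500.0
#: Drive-time cut-offs in minutes.
DEFAULT_THRESHOLDS = (15.0, 30.0, 45.0)


class Scenario(str, Enum):
    """Traffic scenario: congested (peak) or free-flow (off-peak) hours."""

    PEAK = "peak"
    OFF_PEAK = "off_peak"

    @classmethod
    def coerce(cls, value: "Scenario | str") -> "Scenario":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown scenario {value!r}; expected 'peak' or 'off_peak'"
            ) from None


@dataclass
class TravelTimeField:
    """Minutes from one facility to every grid cell under one scenario.

    Unreachable cells carry ``+inf``.
    """

    facility_id: str
    scenario: Scenario
    times: dict[str, float]

    def __post_init__(self) -> None:
        for cid, t in self.times.items():
            if math.isfinite(t) and t < 0:
                raise ValueError(f"negative travel time for cell {cid}")


@dataclass
class Catchment:
    """Cells within ``tt0`` minutes of a facility, and their population."""

    facility_id: str
    scenario: Scenario
    tt0: float
    member_cells: frozenset[str]
    catchment_population: float


def snap_to_network(
    point: tuple[float, float],
    network: RoadNetwork,
    max_snap: float = MAX_SNAP,
    walk_speed: float = WALK_SPEED,
) -> tuple[object, float] | None:
    """Nearest road node to a point, with the walking access time to it.

    Returns ``None`` when the nearest node is farther than ``max_snap``
    (the point is off-network and therefore unreachable).
    """
    if network.n_nodes == 0:
        raise ValueError("cannot snap to an empty network")
    nodes, xy = network.node_coordinates()
    d = np.hypot(xy[:, 0] - point[0], xy[:, 1] - point[1])
    i = int(np.argmin(d))
    if d[i] > max_snap:
        return None
    return nodes[i], float(d[i] / walk_speed)


class NetworkRouter:
    """Shortest-path travel times on a road network, vectorised over facilities.

    Precomputes the sparse cost matrix per scenario and the KD-tree snap of
    every grid cell, so that fields for many facilities are a single
    multi-source Dijkstra call.
    """

    def __init__(
        self,
        network: RoadNetwork,
        grid: PopulationGrid,
        max_snap: float = MAX_SNAP,
        walk_speed: float = WALK_SPEED,
    ):
        self.network = network
        self.grid = grid
        self.max_snap = float(max_snap)
        self.walk_speed = float(walk_speed)
        self._nodes, self._xy = network.node_coordinates()
        self._index = {n: i for i, n in enumerate(self._nodes)}
        self._tree = cKDTree(self._xy) if len(self._nodes) else None
        # cell snaps: nearest node index and walking access time per cell
        if self._tree is not None and len(grid):
            d, idx = self._tree.query(np.column_stack([grid.x, grid.y]))
            self._cell_node = np.where(d <= max_snap, idx, -1)
            self._cell_access = d / walk_speed
        else:
            self._cell_node = np.full(len(grid), -1, dtype=int)
            self._cell_access = np.zeros(len(grid))
        self._cost = {s: self._cost_matrix(s) for s in Scenario}

    def _cost_matrix(self, scenario: Scenario) -> csr_matrix:
        n = len(self._nodes)
        rows, cols, data = [], [], []
        for u, v, d in self.network.graph.edges(data=True):
            t = d["length"] / d["free_flow_speed"]
            if scenario is Scenario.PEAK:
                t *= d["peak_multiplier"]
            if t < 0:
                raise ValueError(f"negative edge cost on ({u}, {v})")
            i, j = self._index[u], self._index[v]
            rows += [i, j]
            cols += [j, i]
            data += [t, t]
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def snap_facility(self, facility: Facility) -> tuple[int, float] | None:
        """Node index and walking access time for a facility, or None if off-network."""
        if self._tree is None:
            raise ValueError("cannot snap to an empty network")
        d, i = self._tree.query([facility.x, facility.y])
        if d > self.max_snap:
            return None
        return int(i), float(d / self.walk_speed)

    def fields(
        self, facilities: list[Facility], scenario: Scenario | str
    ) -> list[TravelTimeField]:
        """Travel-time fields for many facilities with one Dijkstra sweep."""
        scenario = Scenario.coerce(scenario)
        snaps = [self.snap_facility(f) for f in facilities]
        sources = sorted({s[0] for s in snaps if s is not None})
        if sources:
            node_times = dijkstra(
                self._cost[scenario], directed=False, indices=sources
            )
            row_of = {src: r for r, src in enumerate(sources)}
        cells = self.grid.cell_ids.tolist()
        out = []
        for fac, snap in zip(facilities, snaps):
            if snap is None:
                times = {cid: math.inf for cid in cells}
            else:
                node_idx, fac_access = snap
                t_nodes = node_times[row_of[node_idx]]
                reach = self._cell_node >= 0
                total = np.full(len(cells), np.inf)
                total[reach] = (
                    fac_access
                    + t_nodes[self._cell_node[reach]]
                    + self._cell_access[reach]
                )
                times = dict(zip(cells, total.tolist()))
            out.append(TravelTimeField(fac.facility_id, scenario, times))
        return out


def travel_time_field(
    facility: Facility,
    network: RoadNetwork,
    grid: PopulationGrid,
    scenario: Scenario | str,
    max_snap: float = MAX_SNAP,
    walk_speed: float = WALK_SPEED,
) -> TravelTimeField:
    """Travel-time field from one facility to every cell of the grid."""
    router = NetworkRouter(network, grid, max_snap=max_snap, walk_speed=walk_speed)
    return router.fields([facility], scenario)[0]


def travel_time_fields(
    facilities: list[Facility],
    network: RoadNetwork,
    grid: PopulationGrid,
    scenario: Scenario | str,
    max_snap: float = MAX_SNAP,
    walk_speed: float = WALK_SPEED,
) -> list[TravelTimeField]:
    router = NetworkRouter(network, grid, max_snap=max_snap, walk_speed=walk_speed)
    return router.fields(facilities, scenario)


def build_catchment(
    field: TravelTimeField, grid: PopulationGrid, tt0: float
) -> Catchment:
    """Cells within ``tt0`` minutes (inclusive) and their total population."""
    if tt0 < 0:
        raise ValueError("travel-time threshold must be >= 0")
    pop = grid.population_of()
    members = frozenset(c for c, t in field.times.items() if t <= tt0)
    population = float(sum(pop.get(c, 0.0) for c in members))
    return Catchment(field.facility_id, field.scenario, float(tt0), members, population)
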