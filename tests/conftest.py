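import math

import networkx as nx
import numpy as np
import pytest

from trafficfca import (
    CityConfig,
    Facility,
    PopulationGrid,
    Rect,
    RoadNetwork,
    StaffingProfile,
    Tier,
    default_staffing,
    demo_config,
    generate_city,
)


def make_line_network(
    n_nodes: int = 3,
    spacing: float = 600.0,
    speed: float = 60.0,
    peak_multiplier: float = 1.5,
) -> RoadNetwork:
    """A straight road: nodes at (k*spacing, 0), uniform edges."""
    g = nx.Graph()
    for k in range(n_nodes):
        g.add_node(f"n{k}", x=k * spacing, y=0.0)
    for k in range(n_nodes - 1):
        g.add_edge(
            f"n{k}",
            f"n{k + 1}",
            length=spacing,
            free_flow_speed=speed,
            peak_multiplier=peak_multiplier,
        )
    return RoadNetwork(g)


def grid_on_nodes(network: RoadNetwork, populations=None) -> PopulationGrid:
    """One cell exactly on each road node, so walk-access legs vanish."""
    nodes, xy = network.node_coordinates()
    pops = (
        np.ones(len(nodes)) * 100.0
        if populations is None
        else np.asarray(populations, dtype=float)
    )
    return PopulationGrid(
        cell_ids=np.array([f"c{n}" for n in nodes], dtype=object),
        x=xy[:, 0].astype(float),
        y=xy[:, 1].astype(float),
        population=pops,
        cell_size=100.0,
        extent=Rect(
            xy[:, 0].min() - 50, xy[:, 1].min() - 50,
            xy[:, 0].max() + 50, xy[:, 1].max() + 50,
        ),
    )


def facility_at(x: float, y: float, tier=Tier.PRIMARY, fid="fA") -> Facility:
    return Facility(fid, x, y, tier, default_staffing(tier))


def random_city_config(rng: np.random.Generator, seed: int) -> CityConfig:
    """A small random city for property suites (<= ~400 cells)."""
    side = float(rng.uniform(1_200, 2_000))
    return CityConfig(
        extent=Rect(0.0, 0.0, side, side),
        cell_size=100.0,
        total_population=int(rng.integers(2_000, 30_000)),
        n_facilities_by_tier={
            Tier.PRIMARY: int(rng.integers(1, 6)),
            Tier.SECONDARY: int(rng.integers(1, 4)),
            Tier.TERTIARY: int(rng.integers(1, 3)),
        },
        facility_centrality=float(rng.uniform(0.0, 3.0)),
        peak_multiplier_range=(float(rng.uniform(1.0, 1.5)), float(rng.uniform(2.0, 3.5))),
        road_grid_spacing=float(rng.uniform(300, 500)),
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def demo_city():
    """The small demo city used across integration tests."""
    config = demo_config(seed=42)
    network, grid, facilities = generate_city(config)
    return config, network, grid, facilities


def brute_force_times(network: RoadNetwork, source, scenario: str) -> dict:
    """Shortest-path oracle: exhaustive minimum over all simple paths."""
    g = network.graph
    times = {}
    for target in g.nodes:
        if target == source:
            times[target] = 0.0
            continue
        best = math.inf
        for path in nx.all_simple_paths(g, source, target):
            cost = sum(
                network.edge_time(u, v, scenario) for u, v in zip(path, path[1:])
            )
            best = min(best, cost)
        times[target] = best
    return times
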