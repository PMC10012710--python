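"""Configuration-driven end-to-end pipeline.

Runs generate/ingest -> travel fields -> catchments -> step-1 ratios ->
step-2 surfaces (facility and staff measures) -> coverage summaries,
index bins, edge-buffered summaries and peak/off-peak Z-tests, for every
tier x threshold x scenario, and writes all artifacts plus a run manifest
under the output directory.

Outputs are deterministic: the same configuration and seed produce
byte-identical CSVs (the manifest carries wall-clock timestamps and is
the only non-reproducible file).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from .fca import (
    AccessibilitySurface,
    Measure,
    population_weighted_total,
    restrict_surface,
    step1_ratios,
    step2_surface,
)
from .reporting import (
    EDGE_BUFFER_METERS,
    WHO_STAFF_PER_1000,
    apply_edge_buffer,
    bin_index,
    default_binning,
    format_p,
    round_half_away,
    summarize_access,
    two_proportion_z_test,
)
from .synthetic_city import CityConfig, Facility, PopulationGrid, RoadNetwork, Tier, generate_city
from .travel import (
    DEFAULT_THRESHOLDS,
    MAX_SNAP,
    WALK_SPEED,
    Catchment,
    NetworkRouter,
    Scenario,
    build_catchment,
)

__version__ = "0.1.0"

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    """Everything one accessibility run needs.

    Either ``city`` (a synthetic-city configuration) or all three input
    paths must be provided.
    """

    city: CityConfig | None = None
    network_path: str | None = None
    grid_path: str | None = None
    facilities_path: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    scenarios: tuple[Scenario, ...] = (Scenario.PEAK, Scenario.OFF_PEAK)
    who_threshold: float = WHO_STAFF_PER_1000
    buffer: float = EDGE_BUFFER_METERS
    walk_speed: float = WALK_SPEED
    max_snap: float = MAX_SNAP
    output_dir: str = "out"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if any(t <= 0 for t in self.thresholds) or any(
            b <= a for a, b in zip(self.thresholds, self.thresholds[1:])
        ):
            raise ValueError("thresholds must be positive and strictly increasing")
        self.scenarios = tuple(Scenario.coerce(s) for s in self.scenarios)
        if self.who_threshold <= 0:
            raise ValueError("who_threshold must be > 0")
        if self.city is None and not (
            self.network_path and self.grid_path and self.facilities_path
        ):
            raise ValueError("provide either a city config or all three input paths")


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    version: str
    seed: int
    row_counts: dict[str, int] = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))
        tmp.replace(path)  # atomic on POSIX


@dataclass
class PipelineResult:
    manifest: RunManifest
    network: RoadNetwork
    grid: PopulationGrid
    facilities: list[Facility]
    catchments: dict[tuple[Scenario, float], list[Catchment]]
    surfaces: dict[tuple[Tier, Scenario, float, Measure], AccessibilitySurface]
    summaries: pd.DataFrame
    bins: pd.DataFrame
    ztests: pd.DataFrame


def _load_inputs(
    config: PipelineConfig,
) -> tuple[RoadNetwork, PopulationGrid, list[Facility]]:
    if config.city is not None:
        city = dataclasses.replace(config.city, rng_seed=config.rng_seed)
        return generate_city(city)
    return (
        tio.read_network_graphml(config.network_path),
        tio.read_grid_csv(config.grid_path),
        tio.read_facilities(config.facilities_path),
    )


def compute_surfaces(
    network: RoadNetwork,
    grid: PopulationGrid,
    facilities: list[Facility],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    scenarios: tuple[Scenario, ...] = (Scenario.PEAK, Scenario.OFF_PEAK),
    walk_speed: float = WALK_SPEED,
    max_snap: float = MAX_SNAP,
) -> tuple[
    dict[tuple[Scenario, float], list[Catchment]],
    dict[tuple[Tier, Scenario, float, Measure], AccessibilitySurface],
]:
    """Travel fields -> catchments -> both 2SFCA surfaces, all combinations."""
    router = NetworkRouter(network, grid, max_snap=max_snap, walk_speed=walk_speed)
    by_tier = {t: [f for f in facilities if f.tier == t] for t in Tier}
    catchments: dict[tuple[Scenario, float], list[Catchment]] = {}
    surfaces: dict[tuple[Tier, Scenario, float, Measure], AccessibilitySurface] = {}
    for scenario in scenarios:
        fields = {
            f.facility_id: fld
            for f, fld in zip(facilities, router.fields(facilities, scenario))
        }
        for tt0 in thresholds:
            catch = {
                fid: build_catchment(fld, grid, tt0) for fid, fld in fields.items()
            }
            catchments[(scenario, tt0)] = list(catch.values())
            for tier, members in by_tier.items():
                tier_catch = [catch[f.facility_id] for f in members]
                if not tier_catch:
                    surfaces[(tier, scenario, tt0, Measure.FACILITY)] = (
                        AccessibilitySurface(
                            scenario, tt0, tier, Measure.FACILITY, {},
                            frozenset(grid.cell_ids.tolist()),
                        )
                    )
                    surfaces[(tier, scenario, tt0, Measure.STAFF)] = (
                        AccessibilitySurface(
                            scenario, tt0, tier, Measure.STAFF, {},
                            frozenset(grid.cell_ids.tolist()),
                        )
                    )
                    continue
                fac_supply = {f.facility_id: 1.0 for f in members}
                staff_supply = {
                    f.facility_id: float(f.staffing.total()) for f in members
                }
                for measure, supply in (
                    (Measure.FACILITY, fac_supply),
                    (Measure.STAFF, staff_supply),
                ):
                    ratios = step1_ratios(tier_catch, supply)
                    surfaces[(tier, scenario, tt0, measure)] = step2_surface(
                        ratios, tier_catch, grid, tier, measure
                    )
    return catchments, surfaces


def _summary_rows(
    surfaces: dict,
    grid: PopulationGrid,
    who_threshold: float,
    buffered: bool,
) -> list[dict]:
    rows = []
    for (tier, scenario, tt0, measure), surf in sorted(
        surfaces.items(), key=lambda kv: (kv[0][0].value, kv[0][2], kv[0][1].value)
    ):
        if measure is not Measure.FACILITY:
            continue
        staff = surfaces[(tier, scenario, tt0, Measure.STAFF)]
        s = summarize_access(surf, grid, staff, who_threshold)
        rows.append(
            {
                "tier": tier.value,
                "tt0": tt0,
                "scenario": scenario.value,
                "buffered": buffered,
                "population_with_access": s.population_with_access,
                "share_with_access_pct": s.share_with_access,
                "population_suboptimal_staff": s.population_suboptimal_staff,
                "share_suboptimal_staff_pct": s.share_suboptimal_staff,
            }
        )
    return rows


def _ztest_rows(summaries: pd.DataFrame, total_population: dict[bool, float]) -> list[dict]:
    rows = []
    for (tier, tt0, buffered), sub in summaries.groupby(
        ["tier", "tt0", "buffered"], sort=True
    ):
        peak = sub[sub["scenario"] == "peak"]
        off = sub[sub["scenario"] == "off_peak"]
        if peak.empty or off.empty:
            continue
        n = total_population[buffered]
        if n <= 0:
            continue
        for what, col in (
            ("access", "population_with_access"),
            ("suboptimal_staff", "population_suboptimal_staff"),
        ):
            x1 = float(peak[col].iloc[0])
            x2 = float(off[col].iloc[0])
            zt = two_proportion_z_test(x1, n, x2, n)
            rows.append(
                {
                    "tier": tier,
                    "tt0": tt0,
                    "buffered": buffered,
                    "comparison": what,
                    "peak_population": x1,
                    "off_peak_population": x2,
                    "total_population": n,
                    "z": zt.z_statistic,
                    "p_value": zt.p_value,
                    "p_printed": format_p(zt.p_value),
                }
            )
    return rows


def format_summary_table(summaries: pd.DataFrame, ztests: pd.DataFrame) -> str:
    """Fixed-width coverage table: tier x threshold rows, peak/off-peak columns."""
    lines = [
        f"{'Level':<10}{'Time':>8}  {'Peak':>16}  {'Off-peak':>16}  {'P-value':>8}"
    ]
    unbuf = summaries[~summaries["buffered"]]
    for (tier, tt0), sub in unbuf.groupby(["tier", "tt0"], sort=True):
        peak = sub[sub["scenario"] == "peak"].iloc[0]
        off = sub[sub["scenario"] == "off_peak"].iloc[0]
        if len(ztests):
            zrow = ztests[
                (ztests["tier"] == tier)
                & (ztests["tt0"] == tt0)
                & (ztests["buffered"] == False)  # noqa: E712
                & (ztests["comparison"] == "access")
            ]
            p = zrow["p_printed"].iloc[0] if len(zrow) else ""
        else:
            p = ""

        def cell(row):
            return (
                f"{row['population_with_access']:,.0f} "
                f"({round_half_away(row['share_with_access_pct'])}%)"
            )

        lines.append(
            f"{tier:<10}{f'<= {tt0:.0f} min':>8}  {cell(peak):>16}  "
            f"{cell(off):>16}  {p:>8}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write every artifact under output_dir."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict) or k == "city"
        },
        version=__version__,
        seed=config.rng_seed,
        started_at=started,
    )
    stage = "ingest"
    try:
        network, grid, facilities = _load_inputs(config)
        tio.write_facilities_csv(facilities, out / "facilities.csv")
        tio.write_facilities_geojson(facilities, out / "facilities.geojson")
        tio.write_network_graphml(network, out / "network.graphml")
        tio.write_network_edges_csv(network, out / "network_edges.csv")
        tio.write_grid_csv(grid, out / "grid.csv")
        tio.write_grid_geotiff(grid, out / "grid.tif")
        manifest.row_counts.update(
            facilities=len(facilities),
            grid_cells=len(grid),
            network_nodes=network.n_nodes,
            network_edges=network.graph.number_of_edges(),
        )

        stage = "travel"
        catchments, surfaces = compute_surfaces(
            network,
            grid,
            facilities,
            thresholds=config.thresholds,
            scenarios=config.scenarios,
            walk_speed=config.walk_speed,
            max_snap=config.max_snap,
        )
        all_catch = [c for group in catchments.values() for c in group]
        tio.write_catchments_csv(all_catch, out / "catchments.csv")
        manifest.row_counts["catchments"] = len(all_catch)

        stage = "fca"
        for (tier, scenario, tt0, measure), surf in surfaces.items():
            name = f"surface_{tier.value}_{scenario.value}_{tt0:.0f}_{measure.value}"
            tio.write_surface_csv(surf, grid, out / f"{name}.csv")
        manifest.row_counts["surfaces"] = len(surfaces)

        stage = "report"
        buffered_grid = apply_edge_buffer(grid, buffer=config.buffer)
        rows = _summary_rows(surfaces, grid, config.who_threshold, buffered=False)
        buffered_surfaces = {
            k: restrict_surface(s, buffered_grid) for k, s in surfaces.items()
        }
        if len(buffered_grid):
            rows += _summary_rows(
                buffered_surfaces, buffered_grid, config.who_threshold, buffered=True
            )
        summaries = pd.DataFrame(rows)
        summaries.to_csv(out / "summaries.csv", index=False)

        bin_rows = []
        for (tier, scenario, tt0, measure), surf in sorted(
            surfaces.items(), key=lambda kv: (kv[0][0].value, kv[0][2], kv[0][1].value)
        ):
            if measure is not Measure.FACILITY:
                continue
            for label, population in bin_index(surf, grid).items():
                bin_rows.append(
                    {
                        "tier": tier.value,
                        "tt0": tt0,
                        "scenario": scenario.value,
                        "bin": label,
                        "population": population,
                    }
                )
        bins = pd.DataFrame(bin_rows)
        bins.to_csv(out / "index_bins.csv", index=False)

        totals = {False: grid.total_population, True: buffered_grid.total_population}
        ztests = pd.DataFrame(
            _ztest_rows(summaries, totals),
            columns=[
                "tier",
                "tt0",
                "buffered",
                "comparison",
                "peak_population",
                "off_peak_population",
                "total_population",
                "z",
                "p_value",
                "p_printed",
            ],
        )
        ztests.to_csv(out / "ztests.csv", index=False)
        (out / "summary_table.txt").write_text(
            format_summary_table(summaries, ztests)
        )
        manifest.row_counts.update(summaries=len(summaries), ztests=len(ztests))
    except Exception:
        manifest.finished_at = f"FAILED at stage {stage}"
        manifest.write(out / "manifest.json")
        raise
    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        network=network,
        grid=grid,
        facilities=facilities,
        catchments=catchments,
        surfaces=surfaces,
        summaries=summaries,
        bins=bins,
        ztests=ztests,
    )
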