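"""Readers and writers for the interchange formats.

Facilities travel as CSV or GeoJSON point features; the road network as
GraphML or a CSV edge list; the population grid and accessibility
surfaces as CSV or single-band GeoTIFF; catchments as CSV membership
tables or dissolved GeoJSON polygons. Every writer/reader pair
round-trips losslessly. CSV dialect: comma-separated, UTF-8, '.'
decimal, mandatory header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .fca import AccessibilitySurface, Measure
from .synthetic_city import (
    CityConfig,
    Facility,
    PopulationGrid,
    Rect,
    RoadNetwork,
    StaffingProfile,
    Tier,
    default_staffing,
)
from .travel import Catchment, Scenario

__all__ = [
    "read_facilities",
    "write_facilities_csv",
    "write_facilities_geojson",
    "write_network_graphml",
    "read_network_graphml",
    "write_network_edges_csv",
    "write_grid_csv",
    "read_grid_csv",
    "write_grid_geotiff",
    "write_surface_csv",
    "read_surface_csv",
    "write_surface_geotiff",
    "write_catchments_csv",
    "read_catchments_csv",
    "write_catchments_geojson",
    "read_city_config",
]


# -- facilities -------------------------------------------------------------

_STAFF_COLS = ("nurses_midwives", "clinical_officers", "doctors")


def write_facilities_csv(facilities: list[Facility], path: str | Path) -> None:
    rows = [
        {
            "id": f.facility_id,
            "x": f.x,
            "y": f.y,
            "tier": f.tier.value,
            "nurses_midwives": f.staffing.nurses_midwives,
            "clinical_officers": f.staffing.clinical_officers,
            "doctors": f.staffing.doctors,
        }
        for f in facilities
    ]
    pd.DataFrame(rows, columns=["id", "x", "y", "tier", *_STAFF_COLS]).to_csv(
        path, index=False
    )


def write_facilities_geojson(facilities: list[Facility], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [f.x, f.y]},
            "properties": {
                "id": f.facility_id,
                "tier": f.tier.value,
                "nurses_midwives": f.staffing.nurses_midwives,
                "clinical_officers": f.staffing.clinical_officers,
                "doctors": f.staffing.doctors,
            },
        }
        for f in facilities
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def _facility_from_row(
    fid, x, y, tier, staff: dict | None, where: str
) -> Facility:
    try:
        x, y = float(x), float(y)
    except (TypeError, ValueError):
        raise ValueError(f"{where}: non-numeric coordinates ({x!r}, {y!r})") from None
    try:
        tier = Tier.coerce(tier)
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from None
    if staff is None:
        staffing = default_staffing(tier)
    else:
        staffing = StaffingProfile(**{k: int(staff[k]) for k in _STAFF_COLS})
    return Facility(str(fid), x, y, tier, staffing)


def read_facilities(path: str | Path) -> list[Facility]:
    """Read a facility catalog from CSV or GeoJSON.

    Rows missing staffing columns get the tier-default staffing profile.
    Malformed rows raise with the offending line (CSV) or feature index.
    """
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        payload = json.loads(path.read_text())
        out = []
        for i, feat in enumerate(payload["features"]):
            props = feat["properties"]
            x, y = feat["geometry"]["coordinates"]
            staff = (
                {k: props[k] for k in _STAFF_COLS}
                if all(k in props for k in _STAFF_COLS)
                else None
            )
            out.append(
                _facility_from_row(
                    props["id"], x, y, props["tier"], staff, f"feature {i}"
                )
            )
        return out
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    has_staff = all(c in df.columns for c in _STAFF_COLS)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        staff = {k: getattr(row, k) for k in _STAFF_COLS} if has_staff else None
        # header is line 1, first data row line 2
        out.append(
            _facility_from_row(row.id, row.x, row.y, row.tier, staff, f"line {i + 2}")
        )
    return out


# -- road network -----------------------------------------------------------


def write_network_graphml(network: RoadNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, path)


def read_network_graphml(path: str | Path) -> RoadNetwork:
    return RoadNetwork(nx.read_graphml(path))


def write_network_edges_csv(network: RoadNetwork, path: str | Path) -> None:
    rows = [
        {"u": u, "v": v, **{k: d[k] for k in ("length", "free_flow_speed", "peak_multiplier")}}
        for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["u", "v", "length", "free_flow_speed", "peak_multiplier"]).to_csv(
        path, index=False
    )


# -- population grid --------------------------------------------------------


def write_grid_csv(grid: PopulationGrid, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": grid.cell_ids,
            "x": grid.x,
            "y": grid.y,
            "population": grid.population,
        }
    ).to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> PopulationGrid:
    """Read a population grid; cell size and extent are inferred from the lattice."""
    df = pd.read_csv(path, dtype={"cell_id": str}, float_precision="round_trip")
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    pitches = np.concatenate([np.diff(xs), np.diff(ys)])
    cell_size = float(pitches.min()) if len(pitches) else 100.0
    extent = Rect(
        xs.min() - cell_size / 2,
        ys.min() - cell_size / 2,
        xs.max() + cell_size / 2,
        ys.max() + cell_size / 2,
    )
    return PopulationGrid(
        cell_ids=df["cell_id"].to_numpy(dtype=object),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        population=df["population"].to_numpy(dtype=float),
        cell_size=cell_size,
        extent=extent,
    )


def _raster_from_cells(
    grid: PopulationGrid, values: dict[str, float] | None = None, fill: float = np.nan
) -> np.ndarray:
    """Rasterise per-cell values onto the grid lattice (row 0 = northmost)."""
    xs = np.sort(np.unique(grid.x))
    ys = np.sort(np.unique(grid.y))[::-1]
    col = {x: i for i, x in enumerate(xs)}
    row = {y: i for i, y in enumerate(ys)}
    raster = np.full((len(ys), len(xs)), fill, dtype="float32")
    for cid, x, y, pop in zip(grid.cell_ids, grid.x, grid.y, grid.population):
        v = pop if values is None else values.get(cid, fill)
        raster[row[y], col[x]] = v
    return raster


def _write_geotiff(
    raster: np.ndarray, grid: PopulationGrid, path: str | Path
) -> None:
    cs = grid.cell_size
    # minimal GeoTIFF georeferencing: pixel scale + tie point at the
    # top-left corner of the extent (arbitrary projected CRS, meters)
    extratags = [
        (33550, "d", 3, (cs, cs, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, grid.extent.xmin, grid.extent.ymax, 0.0)),
    ]
    tifffile.imwrite(path, raster, extratags=extratags)


def write_grid_geotiff(grid: PopulationGrid, path: str | Path) -> None:
    """Single-band population raster with planar-meter georeferencing tags."""
    _write_geotiff(_raster_from_cells(grid, fill=0.0), grid, path)


# -- accessibility surfaces -------------------------------------------------


def write_surface_csv(
    surface: AccessibilitySurface, grid: PopulationGrid, path: str | Path
) -> None:
    order = {c: i for i, c in enumerate(grid.cell_ids)}
    xs = dict(zip(grid.cell_ids, grid.x))
    ys = dict(zip(grid.cell_ids, grid.y))
    cells = sorted(set(surface.values) | set(surface.underserved), key=order.get)
    pd.DataFrame(
        {
            "cell_id": cells,
            "x": [xs[c] for c in cells],
            "y": [ys[c] for c in cells],
            "index": [surface.values.get(c, np.nan) for c in cells],
            "underserved": [c in surface.underserved for c in cells],
        }
    ).to_csv(path, index=False)


def read_surface_csv(
    path: str | Path,
    tier: Tier | str,
    scenario: Scenario | str,
    tt0: float,
    measure: Measure | str,
) -> AccessibilitySurface:
    df = pd.read_csv(path, dtype={"cell_id": str})
    served = df[~df["underserved"]]
    return AccessibilitySurface(
        scenario=Scenario.coerce(scenario),
        tt0=float(tt0),
        tier=Tier.coerce(tier),
        measure=Measure(measure),
        values=dict(zip(served["cell_id"], served["index"].astype(float))),
        underserved=frozenset(df.loc[df["underserved"], "cell_id"]),
    )


def write_surface_geotiff(
    surface: AccessibilitySurface, grid: PopulationGrid, path: str | Path
) -> None:
    """Two-band raster: accessibility index and an underserved mask."""
    index = _raster_from_cells(grid, surface.values, fill=np.nan)
    mask = _raster_from_cells(
        grid, {c: 1.0 for c in surface.underserved}, fill=0.0
    )
    _write_geotiff(np.stack([index, mask]), grid, path)


# -- catchments -------------------------------------------------------------


def write_catchments_csv(catchments: list[Catchment], path: str | Path) -> None:
    rows = [
        {
            "facility_id": c.facility_id,
            "scenario": c.scenario.value,
            "tt0": c.tt0,
            "cell_id": cell,
        }
        for c in catchments
        for cell in sorted(c.member_cells)
    ]
    pd.DataFrame(rows, columns=["facility_id", "scenario", "tt0", "cell_id"]).to_csv(
        path, index=False
    )


def read_catchments_csv(path: str | Path, grid: PopulationGrid) -> list[Catchment]:
    """Rebuild catchments (population re-tabulated on the grid) from CSV."""
    df = pd.read_csv(path, dtype={"facility_id": str, "cell_id": str})
    pop = grid.population_of()
    out = []
    for (fid, scen, tt0), sub in df.groupby(
        ["facility_id", "scenario", "tt0"], sort=True
    ):
        members = frozenset(sub["cell_id"])
        out.append(
            Catchment(
                facility_id=fid,
                scenario=Scenario.coerce(scen),
                tt0=float(tt0),
                member_cells=members,
                catchment_population=float(sum(pop.get(c, 0.0) for c in members)),
            )
        )
    return out


def write_catchments_geojson(
    catchments: list[Catchment], grid: PopulationGrid, path: str | Path
) -> None:
    """Dissolve each catchment's member cells into a polygon feature."""
    half = grid.cell_size / 2.0
    xs = dict(zip(grid.cell_ids, grid.x))
    ys = dict(zip(grid.cell_ids, grid.y))
    features = []
    for c in catchments:
        cells = [
            box(xs[m] - half, ys[m] - half, xs[m] + half, ys[m] + half)
            for m in sorted(c.member_cells)
            if m in xs
        ]
        geom = mapping(unary_union(cells)) if cells else None
        features.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "facility_id": c.facility_id,
                    "scenario": c.scenario.value,
                    "tt0": c.tt0,
                    "catchment_population": c.catchment_population,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# -- configuration ----------------------------------------------------------


def read_city_config(path: str | Path) -> CityConfig:
    """Read a city configuration from a YAML key-value file.

    Keys mirror the CityConfig fields; ``extent`` is [xmin, ymin, xmax, ymax].
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "extent" in raw:
        kwargs["extent"] = Rect(*[float(v) for v in raw.pop("extent")])
    if "n_facilities_by_tier" in raw:
        kwargs["n_facilities_by_tier"] = {
            Tier.coerce(k): int(v) for k, v in raw.pop("n_facilities_by_tier").items()
        }
    if "peak_multiplier_range" in raw:
        kwargs["peak_multiplier_range"] = tuple(
            float(v) for v in raw.pop("peak_multiplier_range")
        )
    for key in (
        "cell_size",
        "total_population",
        "facility_centrality",
        "road_grid_spacing",
        "rng_seed",
    ):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown city-config keys: {sorted(raw)}")
    return CityConfig(**kwargs)
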