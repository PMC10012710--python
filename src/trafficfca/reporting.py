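"""Headline summaries: coverage tables, index bins, staffing adequacy and tests.

Turns accessibility surfaces into the analysis outputs: the share of the
population within each drive-time threshold of each facility tier under
peak and off-peak traffic, the distribution of the accessibility index
over tier-appropriate bins, the classification of served population
against the WHO benchmark of 4.45 health professionals per 1,000 people,
an edge-effect correction that drops a boundary band of population cells,
and a pooled two-proportion Z-test comparing peak with off-peak coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .fca import AccessibilitySurface
from .synthetic_city import PopulationGrid, Rect, Tier
from .travel import Scenario

__all__ = [
    "WHO_STAFF_PER_1000",
    "EDGE_BUFFER_METERS",
    "AccessSummary",
    "IndexBinning",
    "ZTestResult",
    "default_binning",
    "summarize_access",
    "bin_index",
    "apply_edge_buffer",
    "two_proportion_z_test",
    "share_difference",
    "facilities_per_100k",
    "percent_share",
    "round_half_away",
    "format_p",
]

#: WHO benchmark: doctors + clinical officers + nurses/midwives per 1,000 people.
WHO_STAFF_PER_1000 = 4.45
#: Width of the boundary band removed for the edge-effect correction, meters.
EDGE_BUFFER_METERS = 2_500.0


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (print convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent_share(part: float, whole: float) -> float:
    """Share of ``part`` in ``whole`` as a percentage."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    return 100.0 * part / whole


@dataclass
class AccessSummary:
    """One row of the coverage table: tier x threshold x scenario."""

    tier: Tier
    tt0: float
    scenario: Scenario
    population_with_access: float
    share_with_access: float  # percent of total grid population
    population_suboptimal_staff: float
    share_suboptimal_staff: float  # percent of population with access

    def rounded_shares(self) -> tuple[int, int]:
        return (
            round_half_away(self.share_with_access),
            round_half_away(self.share_suboptimal_staff),
        )


@dataclass(frozen=True)
class IndexBinning:
    """Tier-appropriate accessibility-index bins.

    ``bin_edges`` (strictly increasing, per-person index values) split
    [0, inf) into len(edges)+1 half-open bins [0, e1), [e1, e2), ...,
    [ek, inf). ``scale_denominator`` only affects the labels (facilities
    per 100 / 10,000 / 100,000 people).
    """

    tier: Tier
    scale_denominator: int
    bin_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges)
        if not edges or any(e <= 0 for e in edges):
            raise ValueError("bin edges must be positive")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "bin_edges", edges)

    def labels(self) -> list[str]:
        per = self.scale_denominator
        edges = [e * per for e in self.bin_edges]
        out = [f"<{edges[0]:g} per {per:,}"]
        for a, b in zip(edges, edges[1:]):
            out.append(f"[{a:g}, {b:g}) per {per:,}")
        out.append(f">={edges[-1]:g} per {per:,}")
        return out


#: Bins reconstructed from the reported index bands: 1 and 2 facilities per
#: 100 people (primary); 1, 2 and 5 per 10,000 (secondary); 1, 2 and 3 per
#: 100,000 (tertiary).
_DEFAULT_BINS: dict[Tier, IndexBinning] = {
    Tier.PRIMARY: IndexBinning(Tier.PRIMARY, 100, (0.01, 0.02)),
    Tier.SECONDARY: IndexBinning(Tier.SECONDARY, 10_000, (1e-4, 2e-4, 5e-4)),
    Tier.TERTIARY: IndexBinning(Tier.TERTIARY, 100_000, (1e-5, 2e-5, 3e-5)),
}


def default_binning(tier: Tier | str) -> IndexBinning:
    return _DEFAULT_BINS[Tier.coerce(tier)]


@dataclass
class ZTestResult:
    """Pooled two-proportion Z-test, two-sided."""

    z_statistic: float
    p_value: float
    x1: float
    n1: float
    x2: float
    n2: float


def two_proportion_z_test(x1: float, n1: float, x2: float, n2: float) -> ZTestResult:
    """Compare two coverage proportions x1/n1 vs x2/n2.

    Pooled standard error, two-sided p from the standard normal, no
    continuity correction. Identical proportions give z = 0, p = 1 exactly
    (including the degenerate all-or-none pools where the standard error
    vanishes).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be > 0")
        if not 0 <= x <= n:
            raise ValueError("successes must satisfy 0 <= x <= n")
    if x1 / n1 == x2 / n2:
        return ZTestResult(0.0, 1.0, x1, n1, x2, n2)
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return ZTestResult(float(z), float(p), x1, n1, x2, n2)


def share_difference(share_offpeak: float, share_peak: float) -> float:
    """Off-peak minus peak coverage share, in percentage points."""
    for s in (share_offpeak, share_peak):
        if not 0 <= s <= 100:
            raise ValueError("shares must be percentages in [0, 100]")
    return share_offpeak - share_peak


def facilities_per_100k(n_facilities: int, population: float) -> float:
    """Facility density per 100,000 people, to one decimal."""
    if population <= 0:
        raise ValueError("population must be > 0")
    return round(n_facilities / population * 100_000, 1)


def summarize_access(
    surface: AccessibilitySurface,
    grid: PopulationGrid,
    staff_surface: AccessibilitySurface | None = None,
    who_threshold: float = WHO_STAFF_PER_1000,
) -> AccessSummary:
    """Coverage and staffing-adequacy row for one tier/threshold/scenario.

    Population with access is everyone in a non-underserved cell. Of
    those, cells whose staff index falls strictly below
    ``who_threshold``/1,000 professionals per person count as sub-optimally
    staffed (an index exactly at the benchmark is optimal).
    """
    if staff_surface is not None and (
        staff_surface.tier != surface.tier
        or staff_surface.scenario != surface.scenario
        or staff_surface.tt0 != surface.tt0
    ):
        raise ValueError("facility and staff surfaces must share tier/scenario/tt0")
    pop = grid.population_of()
    if set(surface.values) - set(pop) or (
        staff_surface is not None and set(staff_surface.values) - set(pop)
    ):
        raise ValueError("surface refers to cells absent from the grid")
    total = grid.total_population
    served = float(sum(pop[c] for c in surface.values))
    if staff_surface is None:
        subopt = 0.0
    else:
        cut = who_threshold / 1_000.0
        subopt = float(
            sum(
                pop[c]
                for c in surface.values
                if staff_surface.values.get(c, 0.0) < cut
            )
        )
    return AccessSummary(
        tier=surface.tier,
        tt0=surface.tt0,
        scenario=surface.scenario,
        population_with_access=served,
        share_with_access=percent_share(served, total) if total > 0 else 0.0,
        population_suboptimal_staff=subopt,
        share_suboptimal_staff=percent_share(subopt, served) if served > 0 else 0.0,
    )


def bin_index(
    surface: AccessibilitySurface,
    grid: PopulationGrid,
    binning: IndexBinning | None = None,
) -> dict[str, float]:
    """Population totals per accessibility-index bin, over cells with access.

    Underserved population is reported under the separate key
    ``"underserved"``; it belongs to no index bin.
    """
    if binning is None:
        binning = default_binning(surface.tier)
    if binning.tier != surface.tier:
        raise ValueError("binning tier does not match the surface tier")
    pop = grid.population_of()
    edges = np.array(binning.bin_edges)
    labels = binning.labels()
    out = {lab: 0.0 for lab in labels}
    for cell, value in surface.values.items():
        b = int(np.searchsorted(edges, value, side="right"))
        out[labels[b]] += pop.get(cell, 0.0)
    out["underserved"] = float(sum(pop.get(c, 0.0) for c in surface.underserved))
    return out


def apply_edge_buffer(
    grid: PopulationGrid, extent: Rect | None = None, buffer: float = EDGE_BUFFER_METERS
) -> PopulationGrid:
    """Drop population cells within ``buffer`` meters of the study-area boundary.

    Mitigates the edge effect: cells near the boundary may really be
    served by facilities outside the study area, so they are removed from
    the demand denominator before recomputing summaries. Facilities are
    not removed. A buffer swallowing the whole extent yields an empty grid
    (with a warning, not an error).
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    if extent is None:
        extent = grid.extent
    keep = (
        (grid.x >= extent.xmin + buffer)
        & (grid.x <= extent.xmax - buffer)
        & (grid.y >= extent.ymin + buffer)
        & (grid.y <= extent.ymax - buffer)
    )
    if not keep.any():
        import warnings

        warnings.warn(
            f"edge buffer of {buffer:g} m removes every cell of the grid",
            stacklevel=2,
        )
    return grid.subset(keep)


def format_p(p: float, floor: float = 0.001) -> str:
    """Print convention for p-values: values below the floor as '<0.001'."""
    return f"<{floor:g}" if p < floor else f"{p:.3g}"
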