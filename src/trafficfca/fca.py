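"""Two-step floating catchment area (2SFCA) core.

Step 1 computes, for each facility f, the ratio of its supply to the
population inside its drive-time catchment:

    R_f = F / sum_{cells i with t(f, i) <= tt0} P_i

where F is 1 for the facility measure or the facility's staff total HP for
the professional measure. Step 2 assigns each population cell the sum of
the ratios of every same-tier facility whose catchment covers it:

    A_i = sum_{f : i in catchment(f)} R_f

Cells inside no catchment of the tier are "underserved" and carry no index.
There is no distance decay inside a catchment: every covered cell is
treated as equally served. Tiers never mix: primary, secondary and
tertiary surfaces are computed from disjoint facility sets.

Facilities whose catchment holds zero population have an undefined ratio
and are excluded from step 2; this leaves every cell's index unchanged (a
covered cell would only ever gain a zero term).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .synthetic_city import PopulationGrid, Tier
from .travel import Catchment, Scenario

__all__ = [
    "Measure",
    "SupplyRatio",
    "AccessibilitySurface",
    "step1_ratios",
    "step2_surface",
    "restrict_surface",
    "population_weighted_total",
]


class Measure(str, Enum):
    """What the index counts per person: facilities (F = 1 each) or staff."""

    FACILITY = "facility_index"
    STAFF = "staff_index"


@dataclass(frozen=True)
class SupplyRatio:
    """Step-1 supply-to-demand ratio for one facility (R_f or R_hp)."""

    facility_id: str
    scenario: Scenario
    tt0: float
    supply: float
    ratio: float  # supply per person in the catchment


@dataclass
class AccessibilitySurface:
    """Per-cell step-2 accessibility index for one tier/scenario/threshold.

    ``values`` maps covered cells to their index (supply units per person);
    ``underserved`` holds the cells inside no catchment of the tier.
    """

    scenario: Scenario
    tt0: float
    tier: Tier
    measure: Measure
    values: dict[str, float]
    underserved: frozenset[str]


def step1_ratios(
    catchments: list[Catchment], supply_of: Mapping[str, float]
) -> list[SupplyRatio]:
    """Supply-to-catchment-population ratio for every facility.

    ``supply_of`` maps facility_id to supplied units (1 per facility for
    the facility measure, the staff total for the professional measure).
    Facilities with an empty or zero-population catchment are skipped.
    """
    out = []
    for c in catchments:
        supply = float(supply_of[c.facility_id])
        if supply < 0:
            raise ValueError(f"negative supply for facility {c.facility_id}")
        if c.catchment_population > 0:
            out.append(
                SupplyRatio(
                    facility_id=c.facility_id,
                    scenario=c.scenario,
                    tt0=c.tt0,
                    supply=supply,
                    ratio=supply / c.catchment_population,
                )
            )
    return out


def step2_surface(
    ratios: list[SupplyRatio],
    catchments: list[Catchment],
    grid: PopulationGrid,
    tier: Tier | str,
    measure: Measure | str = Measure.FACILITY,
) -> AccessibilitySurface:
    """Sum each cell's covering-facility ratios into an accessibility surface.

    ``ratios`` and ``catchments`` must all belong to the given tier and
    share one scenario and threshold; cells covered by no catchment are
    flagged underserved.
    """
    tier = Tier.coerce(tier)
    measure = Measure(measure)
    scenarios = {c.scenario for c in catchments} | {r.scenario for r in ratios}
    tt0s = {c.tt0 for c in catchments} | {r.tt0 for r in ratios}
    if len(scenarios) > 1 or len(tt0s) > 1:
        raise ValueError(
            f"mixed scenarios {scenarios} or thresholds {tt0s} in step-2 inputs"
        )
    if not catchments:
        raise ValueError("step 2 needs at least one catchment (may be empty-membered)")
    scenario = next(iter(scenarios))
    tt0 = next(iter(tt0s))
    ratio_of = {r.facility_id: r.ratio for r in ratios}
    values: dict[str, float] = {}
    for c in catchments:
        r = ratio_of.get(c.facility_id)
        if r is None:  # zero-population catchment: no defined ratio
            continue
        for cell in c.member_cells:
            values[cell] = values.get(cell, 0.0) + r
    covered = frozenset().union(*(c.member_cells for c in catchments))
    all_cells = frozenset(grid.cell_ids.tolist())
    # cells in only zero-population catchments are covered but carry index 0
    for cell in covered:
        values.setdefault(cell, 0.0)
    return AccessibilitySurface(
        scenario=scenario,
        tt0=float(tt0),
        tier=tier,
        measure=measure,
        values=values,
        underserved=all_cells - covered,
    )


def restrict_surface(
    surface: AccessibilitySurface, grid: PopulationGrid
) -> AccessibilitySurface:
    """Restrict a surface to the cells of a (sub-)grid, e.g. after an edge buffer.

    Cell indices are unchanged — only the set of cells entering downstream
    summaries shrinks; ratios are not recomputed.
    """
    cells = set(grid.cell_ids.tolist())
    return AccessibilitySurface(
        scenario=surface.scenario,
        tt0=surface.tt0,
        tier=surface.tier,
        measure=surface.measure,
        values={c: v for c, v in surface.values.items() if c in cells},
        underserved=frozenset(c for c in surface.underserved if c in cells),
    )


def population_weighted_total(
    surface: AccessibilitySurface, grid: PopulationGrid
) -> float:
    """Mass-balance diagnostic: sum of population(cell) * index(cell).

    By construction of the two steps this equals the total supply of
    facilities with a positive-population catchment, exactly.
    """
    pop = grid.population_of()
    return float(sum(pop.get(c, 0.0) * v for c, v in surface.values.items()))
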