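# Methods

## Model overview

The package measures geographic accessibility of healthcare under
traffic congestion with the two-step floating catchment area (2SFCA)
method on a road network. Supply is a catalog of facilities in three
care tiers, each contributing one facility unit and a tier-average
staffing complement; demand is a 100 m population grid. A travel
scenario (peak or off-peak) rescales every edge's traversal time, so
catchments — the set of cells within a 15-, 30- or 45-minute drive of
a facility — shrink under congestion, and every downstream quantity
(supply ratios, accessibility indices, coverage shares) responds.

Assumptions inherited from the analysis design:

- **Equal access within a catchment.** There is no distance decay
  inside the cut-off: a cell 3 minutes from a facility and a cell 29
  minutes away are served identically at `tt0 = 30`. Enhanced variants
  (E2SFCA/3SFCA gravity weights) are deliberately out of scope.
- **Tiers never mix.** Primary, secondary and tertiary surfaces are
  computed from disjoint facility sets; "underserved" is always
  per-tier, per-threshold, per-scenario.
- **Symmetric travel.** The network is undirected, so facility-to-
  population and population-to-facility times coincide; catchments can
  be read either way.
- **Single motorised mode.** One drive-time model; no multimodal
  routing, one-way streets or turn penalties.
- **Staffing is a tier average**, not a per-facility roster: 11 staff
  at primary facilities (8 nurses/midwives, 3 clinical officers, 0
  doctors), 19 at secondary (13/4/2), 328 at tertiary (288/30/10).
  The same catchment populations serve as the demand denominator for
  both the facility and the staff measure.

## Travel model

Travel time from facility *f* to cell *i* is the sum of three legs:

1. walk from the facility to its nearest road node
   (distance / walk speed; default 80 m/min);
2. shortest-path drive over the network, where an edge costs
   `length / free_flow_speed` off-peak and that cost times the edge's
   congestion multiplier (≥ 1) at peak;
3. walk from the cell's nearest node to the cell centroid.

Points farther than `max_snap` (default 500 m) from every node are
off-network; their travel times are `+inf`, they fall in no catchment,
and they surface as underserved. Shortest paths are computed with
Dijkstra's algorithm on a sparse cost matrix (`scipy.sparse.csgraph`),
one multi-source sweep per scenario, which keeps a city of a few
thousand cells and hundreds of facilities at interactive speed. The
cell-to-node snap uses a k-d tree.

Thresholds are inclusive (`t ≤ tt0`), which yields two exact
monotonicity properties that the suite verifies on every generated
city: catchments nest in `tt0`, and the peak catchment is a subset of
the off-peak catchment whenever all multipliers are ≥ 1.

## The 2SFCA steps and their mass balance

Step 1 assigns each facility the ratio `R_f = S_f / P(catchment_f)`.
A facility whose catchment holds zero population has an undefined
ratio and is excluded from step 2; this is behaviourally identical to
assigning it a zero ratio (no covered cell would gain anything) and
keeps ratios well-defined. Step 2 sums covering-facility ratios per
cell. The construction implies an exact conservation identity,

```
Σ_i P_i · A_i = Σ_{f : P(catchment_f) > 0} S_f ,
```

which the tests enforce at 1e-9 relative tolerance across 100 random
cities, both measures, all tiers, thresholds and scenarios. It is the
main guard against double-counting or dropped overlap in step 2.

## Reporting conventions

- Coverage shares are percentages of total grid population; printed
  shares round half away from zero to integer percent.
- Staffing adequacy uses the WHO benchmark of 4.45 professionals per
  1,000 people; a staff index strictly below 0.00445 per person is
  sub-optimal, and exact equality counts as optimal (the published
  class boundaries `<4.45` / `>4.45` leave equality undefined; we
  resolve it upward so the benchmark itself passes).
- Index bins per tier follow the scales at which the three tiers are
  readable: per 100 people (primary; edges 0.01, 0.02 per person),
  per 10,000 (secondary; 1, 2, 5 per 10,000) and per 100,000
  (tertiary; 1, 2, 3 per 100,000). Bins are half-open on the right
  and configurable; underserved population is tabulated separately,
  never in a bin.
- The peak/off-peak comparison is a pooled two-proportion Z-test,
  two-sided, no continuity correction (delegated to
  `statsmodels.stats.proportion.proportions_ztest`; equal proportions
  short-circuit to z = 0, p = 1 so the degenerate all-or-none pools
  are well-defined). Tests calibrate it against an exact enumeration
  oracle — the two-sided tail probability of `|p̂1 − p̂2|` under
  independent binomials at the pooled rate — and require agreement
  within 0.05 for group sizes up to 200.
- The edge-effect correction removes population cells whose centroids
  lie within 2.5 km (configurable) of the study-area boundary, then
  recomputes summaries on the reduced grid. Ratios are **not**
  recomputed and facilities are not removed: the correction narrows
  the demand denominator only. The buffered sub-optimal population is
  not asserted to be smaller — that is an empirical pattern, not a
  theorem. On a rectangular extent the buffer is a rectangular inset,
  and centroids exactly on the inset line are retained.

## Synthetic-city generator

The generator emulates the structure the analysis depends on, not any
particular city's geometry:

- **Road network**: a perturbed lattice (node jitter up to 20% of the
  spacing), edge free-flow speeds uniform on 300–700 m/min (18–42
  km/h, urban arterials). Per-edge congestion multipliers are drawn
  uniformly from the configured range and attenuated toward 1 with
  distance from the centre, so congestion concentrates centrally;
  multipliers never drop below 1. The lattice is connected by
  construction.
- **Facilities**: a uniform point contracted toward the centre by a
  factor `u^centrality` (`u ~ U(0,1)`), giving uniform placement at
  centrality 0 and increasingly centre-dense catalogs as it grows;
  the suite checks that the mean distance from the centre decreases
  in the centrality parameter over 20 seeds. Tier counts match the
  configuration exactly. The city-scale default is 944 primary, 94
  secondary and 4 tertiary facilities over ~4.4 million residents —
  23.7 facilities per 100,000, 91% of them primary.
- **Population**: one multinomial draw of the configured total over
  cell weights that are log-normal (σ = 0.8) with a mild
  centre-gradient factor, so the grid is heterogeneous but peripheries
  stay populated. The multinomial allocation conserves the total
  exactly.
- **Determinism**: a single root seed spawns independent child
  streams for network, facilities and grid, so any stage can be
  regenerated alone and two runs with one seed are byte-identical.

What the generator does **not** emulate: real street hierarchies and
one-way systems, dasymetric population mapping, administrative
boundary shapes, and empirically calibrated congestion profiles.
Passing tests therefore demonstrate the correctness and the
qualitative congestion response of the method — peak coverage never
exceeding off-peak, peripheries underserved at short cut-offs — not
any specific city's published coverage percentages, which depend on
proprietary probe data and the true road graph.

## Problem sizes

The bundled demo city is 20 × 20 cells with 12 facilities — a smoke
fixture on which every cell is reachable within 15 minutes. Property
suites run on batches of randomly configured cities of up to ~400
cells and ~50 road nodes (100 cities for the conservation identity,
30 for the monotonicity suite, 200 random graphs of ≤ 12 nodes for
the shortest-path oracle). The acceptance script's simulation city is
8 × 8 km (6,400 cells, 289 nodes, 68 facilities), a scale at which
the 15-minute cut-off binds and the congestion contrast is visible,
while the whole script completes in a few seconds.

## Known limitations

- Catchments are tabulated on snapped grid cells, not rasterised
  polygons; very coarse networks can misassign cells near `max_snap`.
- The Z-test treats grid populations as independent Bernoulli counts;
  spatial autocorrelation makes its p-values optimistic, as in the
  analysis design it mirrors. No small-area uncertainty is attached
  to shares.
- With no distance decay, the index is discontinuous at the cut-off;
  conclusions can shift between 15/30/45 minutes, which is why all
  three are always reported.
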