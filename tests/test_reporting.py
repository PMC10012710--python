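"""Coverage summaries, index bins, WHO staffing classification,
edge-effect buffer and the two-proportion Z-test."""

import numpy as np
import pytest
from scipy import stats

from trafficfca import (
    AccessibilitySurface,
    IndexBinning,
    Measure,
    PopulationGrid,
    Rect,
    Scenario,
    Tier,
    apply_edge_buffer,
    bin_index,
    default_binning,
    facilities_per_100k,
    percent_share,
    share_difference,
    summarize_access,
    two_proportion_z_test,
)
from trafficfca.reporting import format_p, round_half_away


def exact_two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Exact two-sided oracle by full binomial enumeration under the pooled null."""
    p0 = (x1 + x2) / (n1 + n2)
    observed = abs(x1 / n1 - x2 / n2)
    pmf1 = stats.binom.pmf(np.arange(n1 + 1), n1, p0)
    pmf2 = stats.binom.pmf(np.arange(n2 + 1), n2, p0)
    diff = np.abs(
        np.arange(n1 + 1)[:, None] / n1 - np.arange(n2 + 1)[None, :] / n2
    )
    return float(np.outer(pmf1, pmf2)[diff >= observed - 1e-12].sum())


def make_grid(pops: dict[str, float], cell_size=100.0, extent=None) -> PopulationGrid:
    cells = list(pops)
    n = len(cells)
    return PopulationGrid(
        cell_ids=np.array(cells, dtype=object),
        x=np.arange(n, dtype=float) * cell_size + cell_size / 2,
        y=np.full(n, cell_size / 2),
        population=np.array([pops[c] for c in cells], dtype=float),
        cell_size=cell_size,
        extent=extent or Rect(0, 0, n * cell_size, cell_size),
    )


def surface(values, underserved=(), tier=Tier.PRIMARY, measure=Measure.FACILITY):
    return AccessibilitySurface(
        scenario=Scenario.PEAK,
        tt0=15.0,
        tier=tier,
        measure=measure,
        values=dict(values),
        underserved=frozenset(underserved),
    )


class TestZTest:
    def test_identical_proportions_give_z_zero_p_one(self):
        r = two_proportion_z_test(50, 100, 50, 100)
        assert r.z_statistic == 0.0 and r.p_value == 1.0
        # degenerate all-successes pool as well
        r = two_proportion_z_test(100, 100, 100, 100)
        assert r.p_value == 1.0

    def test_city_scale_peak_vs_off_peak_is_highly_significant(self):
        # 0.8M vs 1.8M of 4.1M residents within 15 min of secondary care
        r = two_proportion_z_test(0.8e6, 4.1e6, 1.8e6, 4.1e6)
        assert r.p_value < 0.001

    def test_moderate_difference_at_n_100(self):
        r = two_proportion_z_test(52, 100, 48, 100)
        assert r.z_statistic == pytest.approx(0.5657, abs=1e-4)
        assert r.p_value == pytest.approx(0.5716, abs=1e-4)

    def test_symmetric_under_group_swap(self):
        a = two_proportion_z_test(30, 80, 50, 120)
        b = two_proportion_z_test(50, 120, 30, 80)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.z_statistic == pytest.approx(-b.z_statistic)

    @pytest.mark.parametrize(
        "x1, n1, x2, n2",
        [(52, 100, 48, 100), (10, 40, 20, 40), (75, 150, 90, 150), (5, 200, 15, 200)],
    )
    def test_close_to_exact_binomial_enumeration(self, x1, n1, x2, n2):
        p_z = two_proportion_z_test(x1, n1, x2, n2).p_value
        p_exact = exact_two_proportion_p(x1, n1, x2, n2)
        assert abs(p_z - p_exact) <= 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_z_test(11, 10, 1, 10)

    def test_p_value_print_convention(self):
        assert format_p(1e-7) == "<0.001"
        assert format_p(0.04) == "0.04"


class TestArithmeticHelpers:
    def test_off_peak_minus_peak_share_gains(self):
        assert share_difference(48, 45) == 3
        assert share_difference(43, 20) == 23
        assert share_difference(30, 17) == 13
        assert share_difference(50, 50) == 0
        with pytest.raises(ValueError):
            share_difference(101, 50)

    def test_facility_density_per_100k(self):
        assert facilities_per_100k(1_042, 4.4e6) == 23.7
        assert facilities_per_100k(1, 100_000) == 1.0
        with pytest.raises(ValueError):
            facilities_per_100k(1, 0)

    def test_primary_share_rounds_to_91_percent(self):
        assert round_half_away(percent_share(944, 1_042)) == 91

    def test_round_half_away_from_zero(self):
        assert round_half_away(42.857) == 43
        assert round_half_away(0.5) == 1
        assert round_half_away(2.5) == 3
        assert round_half_away(-0.5) == -1


class TestSummarizeAccess:
    def test_saturated_city_has_full_access_and_no_staff_gap(self):
        grid = make_grid({"c1": 100.0, "c2": 200.0})
        fac = surface({"c1": 0.01, "c2": 0.01})
        staff = surface({"c1": 0.005, "c2": 0.006}, measure=Measure.STAFF)
        s = summarize_access(fac, grid, staff)
        assert s.share_with_access == 100.0
        assert s.population_suboptimal_staff == 0.0

    def test_share_with_access_rounds_like_the_printed_tables(self):
        grid = make_grid({"c1": 100.0, "c2": 200.0, "c3": 400.0})
        fac = surface({"c1": 0.01, "c2": 0.01}, underserved={"c3"})
        s = summarize_access(fac, grid)
        assert s.share_with_access == pytest.approx(300 / 700 * 100)
        assert s.rounded_shares()[0] == 43

    def test_staff_index_exactly_at_the_benchmark_is_optimal(self):
        grid = make_grid({"c1": 1_000.0, "c2": 1_000.0})
        fac = surface({"c1": 0.001, "c2": 0.001})
        staff = surface({"c1": 0.00445, "c2": 0.00444999}, measure=Measure.STAFF)
        s = summarize_access(fac, grid, staff)
        assert s.population_suboptimal_staff == 1_000.0  # only the strictly-below cell

    def test_mismatched_surfaces_rejected(self):
        grid = make_grid({"c1": 1.0})
        fac = surface({"c1": 0.1})
        staff = AccessibilitySurface(
            Scenario.OFF_PEAK, 15.0, Tier.PRIMARY, Measure.STAFF, {"c1": 0.1}, frozenset()
        )
        with pytest.raises(ValueError, match="share"):
            summarize_access(fac, grid, staff)

    def test_surface_cells_must_exist_in_the_grid(self):
        grid = make_grid({"c1": 1.0})
        with pytest.raises(ValueError, match="absent"):
            summarize_access(surface({"zz": 0.1}), grid)


class TestBinIndex:
    def test_below_one_per_100_people_lands_in_the_lowest_bin(self):
        grid = make_grid({"c1": 50.0, "c2": 70.0})
        out = bin_index(surface({"c1": 0.005, "c2": 0.009}), grid)
        assert out["<1 per 100"] == 120.0
        assert out["underserved"] == 0.0

    def test_two_per_100_people_is_the_top_band(self):
        grid = make_grid({"c1": 10.0})
        out = bin_index(surface({"c1": 0.02}), grid)
        assert out[">=2 per 100"] == 10.0

    def test_tertiary_two_per_100k_band(self):
        grid = make_grid({"c1": 10.0})
        out = bin_index(surface({"c1": 2.0e-5}, tier=Tier.TERTIARY), grid)
        assert out["[2, 3) per 100,000"] == 10.0

    def test_underserved_population_reported_separately(self):
        grid = make_grid({"c1": 5.0, "c2": 9.0})
        out = bin_index(surface({"c1": 0.005}, underserved={"c2"}), grid)
        assert out["underserved"] == 9.0

    def test_bad_bin_edges_rejected(self):
        with pytest.raises(ValueError):
            IndexBinning(Tier.PRIMARY, 100, (0.02, 0.01))
        with pytest.raises(ValueError):
            IndexBinning(Tier.PRIMARY, 100, ())

    def test_binning_tier_must_match_surface(self):
        grid = make_grid({"c1": 1.0})
        with pytest.raises(ValueError, match="tier"):
            bin_index(surface({"c1": 0.1}), grid, default_binning(Tier.SECONDARY))


class TestEdgeBuffer:
    def _grid_10km(self):
        # 10 km x 10 km extent, 1 km cells
        pops = {}
        xs, ys, ids = [], [], []
        for r in range(10):
            for c in range(10):
                ids.append(f"c{r}_{c}")
                xs.append(c * 1_000 + 500.0)
                ys.append(r * 1_000 + 500.0)
        return PopulationGrid(
            cell_ids=np.array(ids, dtype=object),
            x=np.array(xs),
            y=np.array(ys),
            population=np.ones(100),
            cell_size=1_000.0,
            extent=Rect(0, 0, 10_000, 10_000),
        )

    def test_zero_buffer_is_identity(self):
        grid = self._grid_10km()
        out = apply_edge_buffer(grid, buffer=0.0)
        assert len(out) == len(grid)

    def test_2500m_buffer_keeps_the_interior(self):
        grid = self._grid_10km()
        out = apply_edge_buffer(grid, buffer=2_500.0)
        # centroids in the closed interior 5 km x 5 km square survive,
        # including those exactly at the 2.5 km line
        assert len(out) == 36
        assert out.x.min() >= 2_500 and out.x.max() <= 7_500
        assert out.y.min() >= 2_500 and out.y.max() <= 7_500

    def test_buffer_swallowing_the_extent_warns_and_empties(self):
        grid = self._grid_10km()
        with pytest.warns(UserWarning, match="removes every cell"):
            out = apply_edge_buffer(grid, buffer=5_000.0)
        assert len(out) == 0

    def test_buffered_population_never_exceeds_unbuffered(self):
        grid = self._grid_10km()
        for buf in (0.0, 1_000.0, 2_500.0, 4_000.0):
            assert apply_edge_buffer(grid, buffer=buf).total_population <= grid.total_population
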