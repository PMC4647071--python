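import numpy as np
import pytest

from dgnet.connectivity import (
    PathwaySpec, build_connectivity, conduction_delay, default_pathway_specs,
    mossy_cell_extent, randomize_topography, terminal_field_density,
    wire_pathway,
)
from dgnet.errors import ConfigurationError, WiringError
from dgnet.populations import ScaleSpec, build_layout


class TestTerminalFields:
    @pytest.mark.parametrize("pre_type", ["MEC", "LEC", "GC", "BC", "MC"])
    def test_density_integrates_to_one(self, pre_type):
        fld = terminal_field_density(pre_type, 5.0, 10.0)
        x = np.linspace(0, 10, 20001)
        integral = np.trapezoid(fld.density(x), x)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_mossy_extent_septal_and_temporal_poles(self):
        # septal pole: 2/3 of a 10 mm axis; temporal pole: 1/3
        assert mossy_cell_extent(0.0, 10.0) == pytest.approx(6.667, abs=0.01)
        assert mossy_cell_extent(10.0, 10.0) == pytest.approx(3.333, abs=0.01)
        mid = mossy_cell_extent(5.0, 10.0)
        assert 3.34 < mid < 6.66

    def test_ec_field_support_limited(self):
        fld = terminal_field_density("MEC", 5.0, 10.0)
        x = np.linspace(0, 10, 2001)
        d = fld.density(x)
        assert d[np.abs(x - 5.0) > 0.75].max() == 0.0
        assert d[np.abs(x - 5.0) < 0.4].min() > 0.0

    def test_position_outside_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            terminal_field_density("GC", 11.0, 10.0)


class TestConductionDelay:
    def test_zero_distance_is_latency_only(self):
        assert conduction_delay(3.0, 3.0) == pytest.approx(0.8)

    def test_one_mm_at_quarter_meter_per_second(self):
        # 1 mm / 0.25 m/s = 4 ms propagation, plus 0.8 ms latency
        assert conduction_delay(0.0, 1.0, 0.25, 0.8) == pytest.approx(4.8)

    def test_monotone_and_nonnegative(self):
        d = conduction_delay(np.zeros(5), np.array([0, 1, 2, 3, 4.0]))
        assert (np.diff(d) > 0).all()
        assert (d >= 0.8).all()

    def test_invalid_velocity(self):
        with pytest.raises(ConfigurationError):
            conduction_delay(0.0, 1.0, 0.0)


@pytest.fixture(scope="module")
def small_layout():
    counts = {"MEC": 40_000, "LEC": 40_000, "GC": 300_000, "BC": 10_000, "MC": 20_000}
    return build_layout(ScaleSpec(0.002), counts, seed=3)


class TestWiring:
    def test_in_degrees_within_table_ranges(self, small_layout):
        graph = build_connectivity(small_layout, include_mc=True, seed=3)
        for edges in graph:
            lo, hi = edges.spec.convergence
            deg = edges.in_degree()
            assert deg.min() >= lo and deg.max() <= hi

    def test_laminar_targets(self, small_layout):
        specs = default_pathway_specs()
        assert specs["MEC_GC"].target_region == "middle"
        assert specs["LEC_GC"].target_region == "outer"
        assert specs["MC_GC"].target_region == "inner"
        assert specs["BC_GC"].target_region == "soma"

    def test_wiring_deterministic(self, small_layout):
        spec = default_pathway_specs()["MEC_GC"]
        a = wire_pathway(small_layout, spec, seed=5)
        b = wire_pathway(small_layout, spec, seed=5)
        np.testing.assert_array_equal(a.pre_idx, b.pre_idx)
        np.testing.assert_array_equal(a.n_syn, b.n_syn)
        c = wire_pathway(small_layout, spec, seed=6)
        assert not np.array_equal(a.n_syn, c.n_syn)

    def test_connection_distance_bounded_by_field(self, small_layout):
        spec = default_pathway_specs()["MEC_GC"]
        edges = wire_pathway(small_layout, spec, seed=5)
        pre = small_layout.septotemporal("MEC")[edges.pre_idx]
        post = small_layout.septotemporal("GC")[edges.post_idx]
        assert np.abs(pre - post).max() <= 0.75 + 1e-9  # half the 1.5 mm max

    def test_empty_pre_population_raises(self, small_layout):
        spec = PathwaySpec(
            name="MEC_GC", pre="MEC", post="GC", target_region="middle",
            convergence=(2, 4), weight=1.0, tau_rise=1.0, tau_fall=5.0, e_rev=0.0,
        )
        layout = build_layout(ScaleSpec(0.002), {"MEC": 500}, seed=1)
        layout.positions["MEC"] = np.empty((0, 2))
        with pytest.raises(WiringError):
            wire_pathway(layout, spec, seed=0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            PathwaySpec(
                name="x", pre="GC", post="BC", target_region="outer",
                convergence=(1, 2), weight=1.0, tau_rise=0.1, tau_fall=0.6,
                e_rev=0.0,
            )


class TestRandomizeTopography:
    def test_degree_preserved_and_distance_increases(self, small_layout):
        spec = default_pathway_specs()["MC_GC"]
        edges = wire_pathway(small_layout, spec, seed=4)
        rand = randomize_topography(edges, small_layout, seed=4)
        np.testing.assert_array_equal(edges.in_degree(), rand.in_degree())

        def mean_dist(e):
            pre = small_layout.septotemporal("MC")[e.pre_idx]
            post = small_layout.septotemporal("GC")[e.post_idx]
            return np.average(np.abs(pre - post), weights=e.n_syn)

        d_topo, d_rand = mean_dist(edges), mean_dist(rand)
        assert d_rand > d_topo
        # uniform resampling on a 10 mm axis: E|x - y| ~ L/3
        assert d_rand == pytest.approx(10.0 / 3.0, rel=0.15)

    def test_randomization_deterministic(self, small_layout):
        spec = default_pathway_specs()["MC_GC"]
        edges = wire_pathway(small_layout, spec, seed=4)
        a = randomize_topography(edges, small_layout, seed=9)
        b = randomize_topography(edges, small_layout, seed=9)
        np.testing.assert_array_equal(a.pre_idx, b.pre_idx)
        np.testing.assert_array_equal(a.n_syn, b.n_syn)
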