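import numpy as np
import pytest

from dgnet.engine import SpikeRaster, simulate, total_spikes
from dgnet.errors import ConfigurationError, ResourceError
from dgnet.stimulus import StimulusSpec


@pytest.fixture(scope="module")
def short_run(tiny_network):
    layout, graph = tiny_network
    return simulate(layout, graph, duration_ms=600.0, seed=11,
                    stimulus=StimulusSpec(rate_hz=5.0, ramp_ms=200.0,
                                          duration_ms=600.0, seed=11))


class TestSimulate:
    def test_decoupled_network_only_ec_spikes(self, tiny_network):
        layout, graph = tiny_network
        res = simulate(layout, graph, duration_ms=500.0, seed=3, weight_scale=0.0)
        assert res.counts["GC"] == 0
        assert res.counts["BC"] == 0
        assert res.counts["MC"] == 0
        assert res.counts["MEC"] + res.counts["LEC"] > 0

    def test_same_seed_identical_rasters(self, tiny_network):
        layout, graph = tiny_network
        a = simulate(layout, graph, duration_ms=500.0, seed=5)
        b = simulate(layout, graph, duration_ms=500.0, seed=5)
        np.testing.assert_array_equal(a.raster.t_ms, b.raster.t_ms)
        np.testing.assert_array_equal(a.raster.cell_id, b.raster.cell_id)

    def test_different_seed_differs(self, tiny_network):
        layout, graph = tiny_network
        a = simulate(layout, graph, duration_ms=500.0, seed=5)
        b = simulate(layout, graph, duration_ms=500.0, seed=6)
        assert len(a.raster) != len(b.raster) or not np.array_equal(
            a.raster.t_ms, b.raster.t_ms
        )

    def test_no_gc_spike_before_first_ec_plus_delay(self, short_run):
        ec_times = np.concatenate([
            short_run.raster.for_population("MEC").t_ms,
            short_run.raster.for_population("LEC").t_ms,
        ])
        gc_times = short_run.raster.for_population("GC").t_ms
        if len(gc_times):
            assert gc_times.min() >= ec_times.min() + 0.8  # synaptic latency

    def test_counts_equal_raster_tallies(self, short_run):
        for pop in ("GC", "BC", "MC"):
            assert short_run.counts[pop] == len(short_run.raster.for_population(pop))

    def test_spike_cap_overflow_raises(self, tiny_network):
        layout, graph = tiny_network
        with pytest.raises(ResourceError):
            simulate(layout, graph, duration_ms=500.0, seed=5, spike_cap=5)

    def test_rejects_large_dt(self, tiny_network):
        layout, graph = tiny_network
        with pytest.raises(ConfigurationError):
            simulate(layout, graph, duration_ms=100.0, dt_ms=0.5)

    def test_unknown_multiplier_pathway(self, tiny_network):
        layout, graph = tiny_network
        with pytest.raises(ConfigurationError):
            simulate(layout, graph, duration_ms=100.0,
                     weight_multipliers={"GC_GC": 2.0})


class TestTotalSpikes:
    def test_full_window_equals_counts(self, short_run):
        assert total_spikes(short_run, "GC") == short_run.counts["GC"]

    def test_window_partition_additivity(self, short_run):
        full = total_spikes(short_run, "MEC")
        parts = sum(
            total_spikes(short_run, "MEC", (a, a + 150.0))
            for a in (0.0, 150.0, 300.0, 450.0)
        )
        assert parts == full

    def test_window_outside_duration_rejected(self, short_run):
        with pytest.raises(ConfigurationError):
            total_spikes(short_run, "GC", (0.0, 1e6))


class TestRasterIO:
    def test_tsv_roundtrip_sorted(self, short_run, tmp_path):
        path = tmp_path / "raster.tsv"
        short_run.raster.save_tsv(path)
        loaded = SpikeRaster.load_tsv(path, duration_ms=short_run.duration_ms)
        assert len(loaded) == len(short_run.raster)
        assert (np.diff(loaded.t_ms) >= 0).all()  # sorted on export
        assert set(np.unique(loaded.population)) == set(
            np.unique(short_run.raster.population)
        )

    def test_positions_match_layout(self, short_run, tiny_network):
        layout, _ = tiny_network
        gc = short_run.raster.for_population("GC")
        if len(gc):
            np.testing.assert_allclose(
                gc.position_mm, layout.septotemporal("GC")[gc.cell_id]
            )
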