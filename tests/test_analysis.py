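import numpy as np
import pytest

from dgnet.analysis import (
    compute_stc, isi_histogram, mean_spectrum, spectral_peak,
    spike_density_matrix, stc_extent,
)
from dgnet.errors import DgnetError
from dgnet.testing import (
    offset_pair_raster, poisson_raster, raster_from_trains, sinusoidal_raster,
    synchronous_raster,
)


class TestSpikeDensityMatrix:
    def test_total_conserved(self):
        r = poisson_raster(n_cells=50, seed=1)
        M, _, _ = spike_density_matrix(r, axis_length_mm=10.0)
        assert M.sum() == len(r)

    def test_single_spike_single_entry(self):
        r = raster_from_trains([np.array([123.0])], np.array([4.2]), 1000.0)
        M, _, _ = spike_density_matrix(r, axis_length_mm=10.0)
        assert (M > 0).sum() == 1
        assert M.max() == 1

    def test_uniform_raster_rows_homogeneous(self):
        # equal numbers of cells per row, equal rates -> row sums multinomial
        rng = np.random.default_rng(2)
        n_cells, rate, dur = 400, 20.0, 4000.0
        trains = [np.sort(rng.uniform(0, dur, rng.poisson(rate * dur / 1000)))
                  for _ in range(n_cells)]
        pos = np.linspace(0.0125, 9.9875, n_cells)
        r = raster_from_trains(trains, pos, dur)
        M, _, _ = spike_density_matrix(r, space_bin_mm=1.0, axis_length_mm=10.0)
        counts = M.sum(axis=1)
        from scipy import stats
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.001


class TestSpectrum:
    def test_constant_rows_flat_after_detrend(self):
        M = np.full((5, 400), 7.0)
        sp = mean_spectrum(M)
        assert np.allclose(sp.magnitude[1:], 0.0)
        assert spectral_peak(sp) is None

    def test_nyquist_for_8ms_bins(self):
        sp = mean_spectrum(np.zeros((2, 500)), time_bin_ms=8.0)
        assert sp.freq_hz[-1] == pytest.approx(62.5)

    def test_injected_modulation_recovered_within_one_bin(self):
        r = sinusoidal_raster(f0_hz=18.0, seed=3)
        M, _, _ = spike_density_matrix(r, space_bin_mm=0.5, axis_length_mm=10.0)
        sp = mean_spectrum(M)
        peak = spectral_peak(sp)
        df = sp.freq_hz[1] - sp.freq_hz[0]
        assert peak is not None
        assert abs(peak["frequency_hz"] - 18.0) <= df

    def test_twenty_hz_modulation(self):
        r = sinusoidal_raster(f0_hz=20.0, seed=4)
        M, _, _ = spike_density_matrix(r, space_bin_mm=0.5, axis_length_mm=10.0)
        peak = spectral_peak(mean_spectrum(M))
        assert peak is not None
        assert peak["frequency_hz"] == pytest.approx(20.0, abs=0.5)

    def test_harmonic_pair_primary_and_secondary(self):
        rng = np.random.default_rng(5)
        t = np.arange(500) * 0.008
        rate = 40 * (1 + 0.8 * np.sin(2 * np.pi * 17.5 * t)
                     + 0.4 * np.sin(2 * np.pi * 35.0 * t))
        M = rng.poisson(np.clip(rate, 0, None), size=(20, 500)).astype(float)
        peak = spectral_peak(mean_spectrum(M))
        assert peak["frequency_hz"] == pytest.approx(17.5, abs=0.5)
        assert peak["secondary_hz"] == pytest.approx(35.0, abs=1.0)

    def test_poisson_raster_has_no_peak(self):
        r = poisson_raster(n_cells=300, rate_hz=10.0, duration_ms=4000.0, seed=6)
        M, _, _ = spike_density_matrix(r, space_bin_mm=0.5, axis_length_mm=10.0)
        assert spectral_peak(mean_spectrum(M)) is None

    def test_row_permutation_invariance(self):
        r = sinusoidal_raster(seed=7)
        M, _, _ = spike_density_matrix(r, space_bin_mm=0.5, axis_length_mm=10.0)
        sp1 = mean_spectrum(M)
        rng = np.random.default_rng(0)
        sp2 = mean_spectrum(M[rng.permutation(M.shape[0])])
        np.testing.assert_allclose(sp1.magnitude, sp2.magnitude)


class TestSTC:
    def test_synchronous_population_correlated_at_all_distances(self):
        r = synchronous_raster(seed=8)
        stc = compute_stc(r, n_sample=50, seed=0)
        zero_lag = np.argmin(np.abs(stc.lags_ms))
        col = stc.corr[:, zero_lag]
        valid = ~np.isnan(col)
        assert np.nanmean(col[valid]) > 0.3  # high correlation everywhere
        # and far apart as strongly as nearby (global synchrony limit)
        far = col[valid][-5:]
        assert np.nanmean(far) > 0.3

    def test_offset_pair_peak_at_offset_lag(self):
        r = offset_pair_raster(offset_ms=15.0, distance_mm=0.3)
        stc = compute_stc(r, n_sample=2, seed=0)
        zero_lag = np.argmin(np.abs(stc.lags_ms))
        occupied = np.nonzero(stc.pair_count[:, zero_lag] > 0)[0]
        assert len(occupied) == 1  # single pair, one distance bin
        row = stc.corr[occupied[0]]
        best_lag = stc.lags_ms[np.nanargmax(row)]
        assert abs(best_lag) == pytest.approx(15.0, abs=2.5)

    def test_single_active_cell_flagged(self):
        r = raster_from_trains(
            [np.arange(10.0, 900.0, 50.0), np.array([])],
            np.array([1.0, 2.0]), 1000.0,
        )
        with pytest.raises(DgnetError):
            compute_stc(r, n_sample=2, seed=0)

    def test_shuffled_positions_flat_in_distance(self):
        r = synchronous_raster(n_cells=60, seed=9)
        rng = np.random.default_rng(1)
        r.position_mm = rng.uniform(0, 10, len(r.position_mm))
        stc = compute_stc(r, n_sample=60, seed=0)
        zero_lag = np.argmin(np.abs(stc.lags_ms))
        col = stc.corr[:, zero_lag]
        valid = ~np.isnan(col) & (stc.pair_count[:, zero_lag] > 20)
        assert np.nanstd(col[valid]) < 0.2 * np.nanmean(col[valid]) + 0.05

    def test_pure_function(self):
        r = sinusoidal_raster(n_cells=30, seed=10)
        a = compute_stc(r, n_sample=30, seed=2)
        b = compute_stc(r, n_sample=30, seed=2)
        np.testing.assert_array_equal(a.corr, b.corr)


class TestSTCExtent:
    def test_delta_correlated_extent_one_bin(self):
        rng = np.random.default_rng(11)
        trains = [np.sort(rng.uniform(0, 2000, 60)) for _ in range(40)]
        pos = rng.uniform(0, 10, 40)
        # make co-located pairs so the zero-distance bin exists
        pos[1] = pos[0] + 0.01
        trains[1] = trains[0].copy()
        r = raster_from_trains(trains, pos, 2000.0)
        ext = stc_extent(compute_stc(r, n_sample=40, seed=0))
        assert ext["spatial_mm"] <= 0.15
        assert ext["temporal_ms"] <= 7.5

    def test_synchronous_raster_has_global_extent(self):
        r = synchronous_raster(n_cells=60, seed=12)
        ext = stc_extent(compute_stc(r, n_sample=60, seed=0))
        assert ext["spatial_mm"] > 5.0


class TestISI:
    def test_single_spike_per_cell_empty(self):
        r = raster_from_trains(
            [np.array([10.0]), np.array([20.0])], np.array([1.0, 2.0]), 100.0
        )
        h = isi_histogram(r, "GC")
        assert h.n_intervals == 0

    def test_periodic_train_single_bin(self):
        r = raster_from_trains(
            [np.arange(0.0, 2000.0, 100.0)], np.array([1.0]), 2000.0
        )
        h = isi_histogram(r, "GC", bin_edges_ms=np.arange(0, 500, 20.0))
        assert (h.counts > 0).sum() == 1
        assert h.counts.max() == 19

    def test_interval_count_identity(self):
        r = poisson_raster(n_cells=40, rate_hz=8.0, seed=13)
        h = isi_histogram(r, "GC", bin_edges_ms=np.arange(0, 1e5, 10.0))
        assert h.n_intervals == h.n_spikes - h.n_active_cells

    def test_poisson_isis_look_exponential(self):
        r = poisson_raster(n_cells=200, rate_hz=5.0, duration_ms=4000.0, seed=14)
        edges = np.arange(0, 1200.0, 50.0)
        h = isi_histogram(r, "GC", bin_edges_ms=edges)
        counts = h.counts[h.counts > 5]
        logc = np.log(counts)
        # log-counts of an exponential distribution decay linearly
        slopes = np.diff(logc)
        assert (slopes < 0).mean() > 0.8
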