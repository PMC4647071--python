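import numpy as np
import pytest

from dgnet.cells import (
    CHANNELS, GATES, build_granule_cell, build_point_cell, build_rate_tables,
    density_table_from_config, gate_inf, granule_scheme, measure_passive,
)
from dgnet.engine import count_somatic_spikes, simulate_single_cell
from dgnet.errors import ConfigurationError


class TestConstruction:
    def test_granule_cell_laminar_densities(self):
        gc = build_granule_cell()
        na = gc.g_chan_uS[CHANNELS.index("sodium")]
        assert na[4] == 0.0            # no sodium in the outer third
        assert na[0] > na[1] > 0       # somatic density dominates
        ka = gc.g_chan_uS[CHANNELS.index("ka")]
        assert ka[0] > 0 and np.all(ka[1:] == 0)  # A-type K somatic only

    def test_granule_scheme_has_five_regions(self):
        scheme = granule_scheme()
        assert scheme.regions == ("soma", "GCL", "inner", "middle", "outer")
        assert len(scheme.g_axial_uS) == 4

    def test_missing_required_block_entry(self):
        with pytest.raises(ConfigurationError):
            density_table_from_config({"Leak (S/cm2)": 1e-4}, 1)

    def test_unknown_point_cell_type(self):
        with pytest.raises(ConfigurationError):
            build_point_cell("PYR")

    def test_mossy_cell_area_as_tabulated(self):
        mc = build_point_cell("MC")
        assert mc.area_cm2[0] == pytest.approx(2.51e-3)

    def test_rate_tables_shapes_and_ranges(self):
        inf, dec = build_rate_tables(0.1)
        assert inf.shape[0] == len(GATES) + 1
        assert np.all((inf >= 0) & (inf <= 1))
        assert np.all((dec[: len(GATES)] > 0) & (dec[: len(GATES)] < 1))

    def test_gates_closed_at_rest(self):
        # Na activation and high-threshold Ca essentially shut at -75 mV
        assert gate_inf("m", -75.0) < 0.01
        assert gate_inf("c", -75.0) < 1e-4
        assert gate_inf("h", -75.0) > 0.9


class TestPassiveProperties:
    def test_granule_cell_rmp_and_tau(self):
        p = measure_passive(build_granule_cell())
        assert p["rmp_mV"] == pytest.approx(-75.01, abs=1.0)
        assert p["tau_m_ms"] == pytest.approx(31.0, rel=0.15)

    def test_mossy_cell_rmp(self):
        p = measure_passive(build_point_cell("MC"))
        assert p["rmp_mV"] == pytest.approx(-64.75, abs=1.0)

    def test_passive_point_cell_analytic_tau(self):
        # tau = Cm / g_leak = 9.8 uF/cm2 / 2.9e-4 S/cm2 = 33.8 ms
        params = {
            "Soma S.A. (cm2)": 1e-4, "R.M.P. (mV)": -70.0,
            "Cm (uF/cm2)": 9.8, "Leak (S/cm2)": 2.9e-4,
            "Sodium (S/cm2)": 0, "Delayed rectifier K (fast)": 0,
        }
        p = measure_passive(build_point_cell("BC", params))
        assert p["tau_m_ms"] == pytest.approx(33.79, rel=0.02)
        assert p["rmp_mV"] == pytest.approx(-70.0, abs=0.05)

    def test_channel_current_zero_at_its_reversal(self):
        # with E_leak set to E_K, a cell carrying only K channels rests
        # exactly at E_K: the K current vanishes at its reversal potential
        from dgnet.cells import E_K
        params = {
            "Soma S.A. (cm2)": 1e-4, "R.M.P. (mV)": E_K,
            "Cm (uF/cm2)": 1.0, "Leak (S/cm2)": 1e-4,
            "Sodium (S/cm2)": 0,
            "Delayed rectifier K (fast)": 0.05,
        }
        cell = build_point_cell("BC", params)
        t, v = simulate_single_cell(cell, 300.0, v0=E_K)
        assert np.abs(v - E_K).max() < 1e-6

    def test_all_zero_densities_rest_at_leak_reversal(self):
        gc = build_granule_cell()
        gc.g_chan_uS = np.zeros_like(gc.g_chan_uS)
        t, v = simulate_single_cell(gc, 400.0, v0=-60.0)
        assert v[-1] == pytest.approx(gc.e_leak, abs=0.05)


class TestDynamics:
    def test_quiescent_without_input(self):
        for cell in ("BC", "MC"):
            n = count_somatic_spikes(build_point_cell(cell), 4000.0)
            assert n == 0
        assert count_somatic_spikes(build_granule_cell(), 4000.0) == 0

    def test_spiking_with_current_step(self):
        n = count_somatic_spikes(
            build_granule_cell(), 600.0, i_step=(0.3, 100.0, 500.0)
        )
        assert n >= 3

    def test_voltage_bounded_under_strong_drive(self):
        t, v = simulate_single_cell(
            build_granule_cell(), 600.0, i_step=(1.0, 100.0, 500.0)
        )
        assert v.max() < 60.0 and v.min() > -120.0

    def test_integration_deterministic(self):
        gc = build_granule_cell()
        _, v1 = simulate_single_cell(gc, 300.0, i_step=(0.2, 50.0, 250.0))
        _, v2 = simulate_single_cell(gc, 300.0, i_step=(0.2, 50.0, 250.0))
        np.testing.assert_array_equal(v1, v2)

    def test_dt_convergence_subthreshold(self):
        gc = build_granule_cell()
        t1, v1 = simulate_single_cell(gc, 400.0, dt_ms=0.1, i_step=(0.05, 100.0, 300.0))
        t2, v2 = simulate_single_cell(gc, 400.0, dt_ms=0.05, i_step=(0.05, 100.0, 300.0))
        assert np.abs(v1 - v2[::2]).max() < 1.0
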