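import numpy as np
import pytest

from dgnet.errors import ConfigurationError, DgnetError
from dgnet.experiments import (
    Scenario, build_network, generate_report, load_rebalance_target,
    named_scenario, paired_activation_curve, pathway_perturb, rebalance,
    run_scenario,
)

TINY = 0.001  # ~500 GC


class TestScenario:
    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ConfigurationError):
            Scenario("x", {"BC_GC": 0.0})

    def test_invalid_topography_rejected(self):
        with pytest.raises(ConfigurationError):
            Scenario("x", topography="shuffled")

    def test_named_registry(self):
        for name in ("baseline", "feedback-strong", "mc-literature",
                     "mc-rebalanced", "mc-random-topo"):
            sc = named_scenario(name, scale=TINY)
            assert sc.name == name
        with pytest.raises(ConfigurationError):
            named_scenario("nonexistent")

    def test_pathway_perturb_composes_with_rebalanced(self):
        sc = pathway_perturb("BC_GC", 0.5, scale=TINY)
        from dgnet.experiments import REBALANCED_MULTIPLIERS
        expected = REBALANCED_MULTIPLIERS.get("BC_GC", 1.0) * 0.5
        assert sc.multipliers["BC_GC"] == pytest.approx(expected)
        assert sc.include_mc


class TestRunScenario:
    def test_identity_scenario_deterministic(self):
        sc = Scenario("ident", {}, scale=TINY, duration_ms=600.0,
                      stimulus_ramp_ms=200.0)
        a = run_scenario(sc, seed=3, analyses=("totals",))
        b = run_scenario(sc, seed=3, analyses=("totals",))
        assert a.totals == b.totals

    def test_report_totals_equal_engine_totals(self):
        sc = Scenario("ident", {}, scale=TINY, duration_ms=600.0,
                      stimulus_ramp_ms=200.0)
        res = run_scenario(sc, seed=4, analyses=("totals",))
        report = generate_report([res])
        assert report["scenarios"][0]["totals"]["GC"] == res.sim.counts["GC"]

    def test_empty_report_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_report([])


class TestRandomizedTopology:
    def test_randomized_mc_changes_wiring_only(self):
        layout_a, graph_a = build_network(scale=TINY, include_mc=True, seed=5)
        layout_b, graph_b = build_network(scale=TINY, include_mc=True, seed=5,
                                          randomized_mc=True)
        np.testing.assert_array_equal(
            layout_a.septotemporal("GC"), layout_b.septotemporal("GC")
        )
        np.testing.assert_array_equal(
            graph_a["MC_GC"].in_degree(), graph_b["MC_GC"].in_degree()
        )
        assert not np.array_equal(
            graph_a["MC_GC"].pre_idx, graph_b["MC_GC"].pre_idx
        )


@pytest.fixture(scope="module")
def tiny_mc_network():
    return build_network(scale=TINY, include_mc=True, seed=9)


class TestPairedActivation:
    def test_long_delays_show_no_interaction(self, tiny_mc_network):
        # once the delay exceeds all synaptic/membrane time constants the
        # conditioning volley's effect is a delay-independent additive
        # contribution: the curve flattens and stays at or above control
        curve = paired_activation_curve(
            {}, [300.0, 400.0], seed=9, network=tiny_mc_network
        )
        p300, p400 = curve["percent_of_control"]
        assert p400 == pytest.approx(p300, abs=5.0)
        assert p400 >= 95.0

    def test_percentages_nonnegative(self, tiny_mc_network):
        curve = paired_activation_curve(
            {}, [20.0, 400.0], seed=9, network=tiny_mc_network
        )
        assert (curve["percent_of_control"] >= 0).all()
        assert curve["control_spikes"] > 0


class TestRebalance:
    def test_target_fixture_shape(self):
        delays, percent = load_rebalance_target()
        assert (np.diff(delays) > 0).all()
        assert percent[0] < percent[-1] <= 110.0

    def test_target_equal_to_initial_returns_initial(self):
        layout, graph = build_network(scale=TINY, include_mc=True, seed=9)
        delays = [30.0, 300.0]
        base = paired_activation_curve({}, delays, seed=9, network=(layout, graph))
        fit = rebalance(delays, base["percent_of_control"], seed=9,
                        network=(layout, graph), max_evals=6)
        assert fit["multipliers"]["BC_GC"] == pytest.approx(1.0)
        assert fit["multipliers"]["MC_GC"] == pytest.approx(1.0)
        # accepted objective values never increase
        assert all(b <= a for a, b in zip(fit["history"], fit["history"][1:]))
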