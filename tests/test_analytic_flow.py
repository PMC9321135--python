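"""Rectangular-duct flow rate, hydraulic resistance, network solving."""

import numpy as np
import pytest

from mfsim.geometry import ChannelGeometry
from mfsim.network import HydraulicNetwork, bifurcation_network, solve_network
from mfsim.poiseuille import (
    hydraulic_resistance,
    plate_flow_rate,
    rect_channel_flow_rate,
    rect_correction_factor,
)


def duct(l=250e-6, w=100e-6, h=100e-6):
    return ChannelGeometry(l=l, w=w, h=h)


class TestFlowRateSeries:
    def test_square_duct_correction_factor(self):
        # frozen from the 200-term series evaluation for w = h
        assert rect_correction_factor(1.0, 1.0, n_terms=200) == pytest.approx(
            0.4217, abs=5e-5
        )
        assert rect_correction_factor(1.0, 1.0, n_terms=2) == pytest.approx(
            0.4217, abs=5e-4
        )

    def test_wide_channel_limit(self):
        # w/h -> inf: the duct tends to parallel plates, factor -> 1
        assert rect_correction_factor(1.0, 1e-4) == pytest.approx(1.0, abs=1e-3)
        g = duct(w=1.0, h=1e-4, l=1.0)
        assert rect_channel_flow_rate(g, 1.0, 1e-3) == pytest.approx(
            g.w * g.h**3 / (12 * 1e-3 * g.l), rel=1e-3
        )

    @pytest.mark.parametrize("aspect", [0.1, 0.25, 0.5, 0.75, 1.0])
    def test_two_term_truncation(self, aspect):
        exact = rect_correction_factor(1.0, aspect, n_terms=200)
        approx = rect_correction_factor(1.0, aspect, n_terms=2)
        assert abs(approx - exact) / exact < 1e-3

    def test_linearity_in_dp(self):
        g = duct()
        assert rect_channel_flow_rate(g, 14.0, 1e-3) == pytest.approx(
            14.0 * rect_channel_flow_rate(g, 1.0, 1e-3)
        )

    def test_wh_swap_symmetry(self):
        # the full series is symmetric under exchanging width and height
        q1 = rect_channel_flow_rate(duct(w=50e-6, h=100e-6), 1.0, 1e-3, n_terms=200)
        q2 = rect_channel_flow_rate(duct(w=100e-6, h=50e-6), 1.0, 1e-3, n_terms=200)
        assert q1 == pytest.approx(q2, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rect_channel_flow_rate(duct(), 1.0, mu=-1.0)
        with pytest.raises(ValueError):
            rect_correction_factor(1.0, 1.0, n_terms=0)


class TestHydraulicResistance:
    def test_independent_of_probe_dp(self):
        g = duct()
        r = hydraulic_resistance(g, 1e-3)
        assert rect_channel_flow_rate(g, 7.0, 1e-3) * r == pytest.approx(7.0)

    def test_length_proportionality(self):
        r1 = hydraulic_resistance(duct(l=250e-6), 1e-3)
        r2 = hydraulic_resistance(duct(l=500e-6), 1e-3)
        assert r2 == pytest.approx(2 * r1)

    def test_matches_brute_force(self):
        g = duct()
        dp = 3.7
        assert hydraulic_resistance(g, 1e-3) == pytest.approx(
            dp / rect_channel_flow_rate(g, dp, 1e-3)
        )

    def test_plate_variant(self):
        g = duct()
        assert hydraulic_resistance(g, 1e-3, dims=2) == pytest.approx(
            1.0 / plate_flow_rate(g, 1.0, 1e-3)
        )


class TestNetwork:
    def test_single_edge_ohm(self):
        net = HydraulicNetwork()
        net.add_edge("a", "b", R=5.0)
        net.fixed_pressure = {"a": 10.0, "b": 0.0}
        sol = solve_network(net)
        assert sol.edge_flow("a->b") == pytest.approx(2.0)

    def test_parallel_branches_split_evenly(self):
        net = HydraulicNetwork()
        net.add_edge("j", "o1", R=3.0, label="b1")
        net.add_edge("j", "o2", R=3.0, label="b2")
        net.fixed_pressure = {"o1": 0.0, "o2": 0.0}
        net.inflow = {"j": 4.0}
        sol = solve_network(net)
        assert sol.edge_flow("b1") == pytest.approx(2.0)
        assert sol.edge_flow("b2") == pytest.approx(2.0)

    def test_bifurcation_direction_and_conservation(self):
        _, sol = bifurcation_network(
            l=500e-6, k=250e-6, w=100e-6, h=100e-6, mu=1.004e-3,
            u_in=0.01, p_top=0.0, p_bot=10.0, dims=3,
        )
        q_in = sol.edge_flow("inlet")
        q_top, q_bot = sol.edge_flow("top"), sol.edge_flow("bot")
        assert q_top > q_bot  # low-pressure branch carries the larger flow
        assert q_top + q_bot == pytest.approx(q_in, rel=1e-12)

    def test_floating_network_rejected(self):
        net = HydraulicNetwork()
        net.add_edge("a", "b", R=1.0)
        net.inflow = {"a": 1.0}
        with pytest.raises(ValueError, match="ill-posed"):
            solve_network(net)

    @pytest.mark.parametrize("seed", range(100))
    def test_random_networks_conserve_flow(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = rng.integers(3, 10)
        nodes = [f"n{i}" for i in range(n_nodes)]
        net = HydraulicNetwork()
        # spanning tree + extra edges keeps it connected, <= 20 edges
        for i in range(1, n_nodes):
            j = rng.integers(0, i)
            net.add_edge(nodes[i], nodes[j], R=float(rng.uniform(0.1, 10)), label=f"t{i}")
        for e in range(rng.integers(0, 10)):
            i, j = rng.integers(0, n_nodes, 2)
            if i != j:
                net.add_edge(nodes[i], nodes[j], R=float(rng.uniform(0.1, 10)), label=f"x{e}")
        net.fixed_pressure = {nodes[0]: float(rng.normal())}
        for i in range(1, n_nodes):
            if rng.random() < 0.3:
                net.inflow[nodes[i]] = float(rng.normal())
        sol = solve_network(net)
        # Kirchhoff balance at every non-fixed node
        for n in nodes[1:]:
            total = net.inflow.get(n, 0.0)
            for e in net.edges:
                q = sol.flows[e.label or f"{e.a}->{e.b}"]
                if e.a == n:
                    total -= q
                if e.b == n:
                    total += q
            assert abs(total) < 1e-9 * max(1.0, abs(sol.pressures[n]))
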