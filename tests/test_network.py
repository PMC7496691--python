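"""Structure, rate evaluation, RHS assembly and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import cyclekin as ck
from cyclekin.network import FlowConfig, MassAction, Reaction, ReactionNetwork

from conftest import rational_left_nullspace, spans_equal


class TestStoichiometricMatrix:
    def test_landolt_columns(self, landolt_net):
        # species order (A,B,C,D); note the +2 for C in the fast step
        expected = np.array(
            [[-1, 0, -1], [-1, -1, 0], [1, -1, 2], [0, 1, -1]]
        )
        assert np.array_equal(landolt_net.stoichiometry, expected)

    def test_single_reaction(self):
        net = ReactionNetwork(
            ["A", "B"], [Reaction({"A": 1}, {"B": 1}, MassAction(1.0))]
        )
        assert np.array_equal(net.stoichiometry, [[-1], [1]])

    def test_hypercycle_cross_step_column(self, hypercycle_base_net):
        net = hypercycle_base_net
        assert net.stoichiometry.shape == (10, 10)
        # AZ + B -> C + Z
        j = [r.label for r in net.reactions].index("AZ + B -> C + Z")
        col = net.stoichiometry[:, j]
        expected = {"AZ": -1, "B": -1, "C": 1, "Z": 1}
        for i, sp in enumerate(net.species):
            assert col[i] == expected.get(sp, 0)

    def test_unknown_species_rejected(self):
        with pytest.raises(ck.NetworkStructureError):
            ReactionNetwork(["A"], [Reaction({"A": 1}, {"Q": 1}, MassAction(1.0))])

    def test_duplicate_species_rejected(self):
        with pytest.raises(ck.NetworkStructureError):
            ReactionNetwork(["A", "A"], [])


class TestEvaluateRates:
    def test_mass_action_product(self, landolt_net):
        c = landolt_net.state({"B": 1.0, "C": 0.5})
        v = ck.evaluate_rates(landolt_net, c)
        assert v[1] == pytest.approx(1e-2 * 1.0 * 0.5)

    def test_zero_reactant_gives_zero_rate(self, landolt_net):
        v = ck.evaluate_rates(landolt_net, np.zeros(4))
        assert np.all(v == 0.0)

    def test_empirical_law_at_zero_autocatalyst(self):
        net = ck.empirical_autocatalysis(1e-13, 8e-3, 0.5)
        v = ck.evaluate_rates(net, net.state({"A": 1.0, "B": 1.0}))
        # 0^0.5 defined as 0: only the direct term remains
        assert v[0] == 1e-13

    def test_empirical_law_fractional_order(self):
        net = ck.empirical_autocatalysis(1e-13, 8e-3, 0.5)
        c = net.state({"A": 1.0, "B": 1.0, "C": 0.25})
        v = ck.evaluate_rates(net, c)
        assert v[0] == pytest.approx(1e-13 + 8e-3 * 0.5, rel=1e-12)

    def test_negative_beyond_tolerance_raises(self, landolt_net):
        with pytest.raises(ck.NumericalStateError):
            ck.evaluate_rates(landolt_net, np.array([1.0, -1e-6, 0.0, 0.0]))

    def test_small_negative_clipped(self, landolt_net):
        c = np.array([1.0, -1e-12, 0.0, 0.0])
        assert np.all(ck.evaluate_rates(landolt_net, c) >= 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        alpha=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=1e-6, max_value=10.0),
        c=st.floats(min_value=1e-6, max_value=10.0),
    )
    def test_first_order_homogeneity(self, landolt_net, alpha, b, c):
        """Scaling one first-order reactant scales the rate by exactly alpha."""
        base = landolt_net.state({"B": b, "C": c})
        scaled = landolt_net.state({"B": alpha * b, "C": c})
        v0 = ck.evaluate_rates(landolt_net, base)[1]
        v1 = ck.evaluate_rates(landolt_net, scaled)[1]
        assert v1 == pytest.approx(alpha * v0, rel=1e-12)


class TestAssembleRhs:
    def test_landolt_initial_derivatives(self, landolt_net):
        c = landolt_net.state({"A": 1.0, "B": 1.0})
        dcdt = ck.assemble_rhs(landolt_net, c)
        assert dcdt[landolt_net.index["C"]] == pytest.approx(1e-6)
        assert dcdt[landolt_net.index["A"]] == pytest.approx(-1e-6)

    def test_zero_rates_at_feed_is_stationary(self):
        net = ck.landolt(0.0, 0.0, 0.0)
        feed = net.state({"A": 1.0, "B": 1.0})
        flow = FlowConfig(k0=0.1, feed=feed)
        assert np.all(ck.assemble_rhs(net, feed, flow) == 0.0)

    def test_flow_only_relaxation_closed_form(self):
        """With S v = 0 the CSTR relaxes as c = feed + (c0-feed) e^(-k0 t)."""
        net = ck.landolt(0.0, 0.0, 0.0)
        feed = net.state({"A": 1.0, "B": 0.5})
        c0 = net.state({"A": 0.2, "C": 2.0})
        flow = FlowConfig(k0=0.05, feed=feed)
        sol = solve_ivp(net.rhs(flow), (0, 40.0), c0, rtol=1e-10, atol=1e-12)
        expected = feed + (c0 - feed) * np.exp(-0.05 * sol.t[-1])
        assert np.allclose(sol.y[:, -1], expected, atol=1e-8)

    def test_negative_flow_rate_rejected(self):
        net = ck.landolt(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            FlowConfig(k0=-1.0, feed=net.state({}))


class TestConservationLaws:
    def test_landolt_basis_span(self, landolt_net):
        # [A]+[C]+[D] and [B]+[C]+2[D] are the conserved moieties
        laws = ck.conservation_laws(landolt_net)
        assert len(laws) == 2
        assert spans_equal(laws, [(1, 0, 1, 1), (0, 1, 1, 2)])
        for w in laws:
            assert np.all(w @ landolt_net.stoichiometry == 0)

    def test_single_reaction_total(self):
        net = ReactionNetwork(
            ["A", "B"], [Reaction({"A": 1}, {"B": 1}, MassAction(1.0))]
        )
        laws = ck.conservation_laws(net)
        assert spans_equal(laws, [(1, 1)])

    @pytest.mark.parametrize(
        "factory, dim",
        [
            (lambda: ck.landolt(1e-6, 1e-2, 1e7), 2),
            (lambda: ck.supercatalysis_full(1e-5, 1e6, 1e8, 100.0, 1e7), 2),
            (lambda: ck.preset("fig5_optionA").network, 4),
        ],
        ids=["landolt", "supercatalysis", "hypercycle"],
    )
    def test_dimension_matches_rational_oracle(self, factory, dim):
        net = factory()
        laws = ck.conservation_laws(net)
        oracle = rational_left_nullspace(net.stoichiometry)
        assert len(laws) == len(oracle) == dim
        assert spans_equal(laws, oracle)

    def test_hypercycle_A_moiety(self, hypercycle_base_net):
        """The A-containing moiety [A]+[C]+[D]+[AZ]+[XC] is conserved."""
        w = np.array([1, 0, 1, 1, 0, 0, 0, 0, 1, 1])
        assert np.all(w @ hypercycle_base_net.stoichiometry == 0)
        laws = ck.conservation_laws(hypercycle_base_net)
        assert spans_equal(laws + [w], laws)  # w lies in the computed span


def test_autocatalytic_loop_extent_matches_direct_step(landolt_net):
    """One turnover of the B+C/A+D loop has the direct step's stoichiometry."""
    S = landolt_net.stoichiometry
    assert np.array_equal(S @ np.array([0, 1, 1]), S @ np.array([1, 0, 0]))
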