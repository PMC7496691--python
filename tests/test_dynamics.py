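"""Integration, steady-state location, and the derived kinetic metrics."""

import numpy as np
import pytest

import cyclekin as ck
from cyclekin.dynamics import (
    FlowSweepResult,
    SteadyStateResult,
    Trajectory,
    log_k0_grid,
)
from cyclekin.network import FlowConfig


class TestIntegrateBatch:
    def test_complete_conversion_limit(self):
        """Equal initial reactants convert fully: [C] -> 1 M, others -> 0."""
        net = ck.preset("fig2_landolt").network
        traj = ck.integrate_batch(net, net.state({"A": 1.0, "B": 1.0}), 5e4)
        assert traj["C"][-1] == pytest.approx(1.0, abs=1e-6)
        assert traj["A"][-1] == pytest.approx(0.0, abs=1e-6)
        assert traj["D"][-1] == pytest.approx(0.0, abs=1e-6)

    def test_zero_rates_constant_trajectory(self):
        net = ck.landolt(0.0, 0.0, 0.0)
        y0 = net.state({"A": 0.7, "C": 0.1})
        traj = ck.integrate_batch(net, y0, 100.0)
        assert np.allclose(traj.concentrations, y0, atol=1e-14)

    def test_invalid_horizon_rejected(self):
        net = ck.landolt(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            ck.integrate_batch(net, net.state({}), 0.0)

    def test_sigmoid_transition_resolved(self):
        """Grid refinement puts points through the steep ignition region."""
        net = ck.preset("fig2_landolt").network
        traj = ck.integrate_batch(net, net.state({"A": 1.0, "B": 1.0}), 2000.0)
        c = traj["C"]
        assert np.max(np.diff(c)) < 0.05  # no jump larger than 5% of range

    def test_tolerance_metadata_recorded(self):
        net = ck.landolt(1e-6, 1e-2, 1e7)
        traj = ck.integrate_batch(net, net.state({"A": 1, "B": 1}), 10.0)
        assert traj.meta["rtol"] == 1e-8 and traj.meta["atol"] == 1e-12


class TestSteadyStateFlow:
    def test_no_reactions_steady_state_is_feed(self):
        net = ck.landolt(0.0, 0.0, 0.0)
        feed = net.state({"A": 1.0, "B": 0.3})
        st = ck.steady_state_flow(
            net, FlowConfig(k0=0.01, feed=feed), net.state({})
        )
        assert st.converged
        assert np.allclose(st.concentrations, feed, atol=1e-9)

    def test_washout_limit_approaches_feed(self, hypercycle_base_net, hypercycle_init):
        st = ck.steady_state_flow(
            hypercycle_base_net,
            FlowConfig(k0=1e3, feed=hypercycle_init.copy()),
            hypercycle_init,
        )
        assert st.converged
        # corrections are O(rate/k0) ~ 1e-9 relative to the 1 M feed
        assert np.max(np.abs(st.concentrations - hypercycle_init)) < 1e-6

    def test_nonconvergence_is_flagged_not_raised(self, hypercycle_base_net, hypercycle_init):
        st = ck.steady_state_flow(
            hypercycle_base_net,
            FlowConfig(k0=1e-3, feed=hypercycle_init.copy()),
            hypercycle_init,
            t_max=5.0,  # far too short on purpose
            polish=False,
        )
        assert isinstance(st, SteadyStateResult)
        assert not st.converged

    def test_ratio_stable_under_tighter_tolerances(self, hypercycle_base_net, hypercycle_init):
        """Reported selection ratios are solver-tolerance independent."""
        def ratio(rtol, atol):
            st = ck.steady_state_flow(
                hypercycle_base_net,
                FlowConfig(k0=1e-2, feed=hypercycle_init.copy()),
                hypercycle_init,
                rtol=rtol,
                atol=atol,
            )
            c = st.concentrations[hypercycle_base_net.index["C"]]
            z = st.concentrations[hypercycle_base_net.index["Z"]]
            return z / (c + z)

        assert abs(ratio(1e-8, 1e-12) - ratio(1e-9, 1e-13)) < 1e-4


class TestSweepAndTransition:
    def test_grid_helper_density(self):
        grid = log_k0_grid(-4, 0, 25)
        assert len(grid) == 101
        assert grid[0] == pytest.approx(1e-4) and grid[-1] == pytest.approx(1.0)

    def test_unsorted_grid_rejected(self, hypercycle_base_net, hypercycle_init):
        with pytest.raises(ValueError):
            ck.sweep_flow(
                hypercycle_base_net,
                hypercycle_init.copy(),
                np.array([1e-2, 1e-3]),
                hypercycle_init,
            )

    def test_synthetic_ratio_crossing_exact(self):
        """r(k0) = 0.5/(1+k0/1e-2) crosses 0.25 at exactly k0 = 1e-2."""
        grid = log_k0_grid(-4, 0, 10)  # contains 1e-2 exactly
        ratio = 0.5 / (1.0 + grid / 1e-2)
        sweep = FlowSweepResult(k0_grid=grid, states=[], ratio=ratio)
        tr = ck.transition_flow_rate(sweep, level=0.25)
        assert tr.k0 == pytest.approx(1e-2, rel=1e-12)
        assert tr.tau == pytest.approx(100.0, rel=1e-12)

    def test_synthetic_ratio_crossing_interpolated(self):
        grid = log_k0_grid(-4, 0, 7)  # does not contain 1e-2
        ratio = 0.5 / (1.0 + grid / 1e-2)
        tr = ck.transition_flow_rate(
            FlowSweepResult(k0_grid=grid, states=[], ratio=ratio), level=0.25
        )
        assert tr.k0 == pytest.approx(1e-2, rel=0.02)

    def test_flat_ratio_has_no_crossing(self):
        grid = log_k0_grid(-3, 0, 5)
        sweep = FlowSweepResult(
            k0_grid=grid, states=[], ratio=np.full_like(grid, 0.5)
        )
        assert ck.transition_flow_rate(sweep, level=0.25) is None


class TestMetrics:
    def test_conversion_bounds(self):
        net = ck.preset("fig2_landolt").network
        traj = ck.integrate_batch(net, net.state({"A": 1, "B": 1}), 1e-3)
        assert ck.conversion(traj, "C", 1.0) == pytest.approx(0.0, abs=1e-8)
        with pytest.raises(ValueError):
            ck.conversion(traj, "C", 0.0)

    def test_linear_ramp_tangent_is_zero(self):
        t = np.linspace(0, 10, 50)
        traj = Trajectory(times=t, concentrations=(0.3 * t)[:, None], species=["C"])
        assert ck.induction_period(traj, "C") == pytest.approx(0.0, abs=1e-9)

    def test_logistic_tangent_closed_form(self):
        """For c = 1/(1+exp(-(t-t0)/w)) the tangent construction gives t0-2w."""
        t0, w = 400.0, 30.0
        t = np.linspace(0, 1000, 20001)
        c = 1.0 / (1.0 + np.exp(-(t - t0) / w))
        traj = Trajectory(times=t, concentrations=c[:, None], species=["C"])
        assert ck.induction_period(traj, "C") == pytest.approx(t0 - 2 * w, rel=1e-3)

    def test_decreasing_trace_has_no_induction_period(self):
        t = np.linspace(0, 10, 50)
        traj = Trajectory(
            times=t, concentrations=np.exp(-t)[:, None], species=["C"]
        )
        assert ck.induction_period(traj, "C") is None

    def test_threshold_method_crossing(self):
        t = np.linspace(0, 100, 1001)
        c = np.clip((t - 20.0) / 40.0, 0.0, 1.0)  # ramps 0->1 over t in [20,60]
        traj = Trajectory(times=t, concentrations=c[:, None], species=["C"])
        ip = ck.induction_period(traj, "C", method="threshold", threshold=0.05,
                                 reference_conc=1.0)
        assert ip == pytest.approx(22.0, rel=1e-3)

    def test_induction_period_shrinks_with_cross_catalysis(self):
        """More C->Z cross-catalysis ignites Z earlier (5-point grid)."""
        from dataclasses import replace
        from cyclekin.models import FIGURE4_BASE

        previous = np.inf
        for k9 in [3e-7, 1e-4, 1e-3, 1e-1, 10.0]:
            net = ck.hypercycle(replace(FIGURE4_BASE, kXC_cross=k9))
            traj = ck.integrate_batch(
                net, net.state({"A": 1, "B": 1, "X": 1, "Y": 1}), 3000.0
            )
            ip = ck.induction_period(traj, "Z")
            assert ip <= previous + 1e-6
            previous = ip
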