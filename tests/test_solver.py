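"""Network solver: element laws, steady solves, Windkessel integration,
transient solves, conservation and determinism."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import pulmoflow as pf
from pulmoflow.solver import (
    CompiledNetwork,
    SolverError,
    stenosis_loss_coefficient,
)

from conftest import outlets_for, random_outlets, random_tree


class TestElementLaws:
    def test_poiseuille_hand_values(self):
        assert pf.poiseuille_resistance(0.05, 0.01, 3.5e-3) == pytest.approx(
            4.4563e4, rel=1e-4
        )
        assert pf.poiseuille_resistance(0.05, 0.005, 3.5e-3) == pytest.approx(
            7.130e5, rel=1e-3
        )

    def test_poiseuille_radius_scaling(self):
        r1 = pf.poiseuille_resistance(0.05, 0.004, 3.5e-3)
        r2 = pf.poiseuille_resistance(0.05, 0.008, 3.5e-3)
        assert r1 / r2 == pytest.approx(16.0)

    def test_poiseuille_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pf.poiseuille_resistance(0.0, 0.01, 3.5e-3)
        with pytest.raises(ValueError):
            pf.poiseuille_resistance(0.05, -0.01, 3.5e-3)

    def test_stenosis_loss_hand_value(self, fluid):
        dp = pf.stenosis_pressure_loss(1e-4, 3e-4, 1e-4, fluid, kt=1.52)
        assert dp == pytest.approx(356.7, rel=1e-3)

    def test_stenosis_loss_vanishes_without_flow_or_narrowing(self, fluid):
        assert pf.stenosis_pressure_loss(0.0, 3e-4, 1e-4, fluid) == 0.0
        assert pf.stenosis_pressure_loss(1e-4, 3e-4, 3e-4, fluid) == 0.0

    def test_stenosis_loss_is_odd_in_flow(self, fluid):
        dp = pf.stenosis_pressure_loss(1e-4, 3e-4, 1e-4, fluid)
        assert pf.stenosis_pressure_loss(-1e-4, 3e-4, 1e-4, fluid) == -dp

    def test_stenotic_area_cannot_exceed_normal(self, fluid):
        with pytest.raises(ValueError):
            pf.stenosis_pressure_loss(1e-4, 1e-4, 3e-4, fluid)


class TestSteadySolve:
    def test_symmetric_tree_splits_evenly(self, y_tree, fluid):
        outlets = [
            pf.WindkesselOutlet(o, 1e8, 1e-9) for o in y_tree.outlet_ids
        ]
        sol = pf.solve_steady_network(y_tree, outlets, 0.5, fluid)
        q = list(sol.outlet_flows.values())
        assert q[0] == pytest.approx(q[1], rel=1e-12)
        assert sol.mass_balance_error < 1e-12

    def test_series_resistance_hand_computation(self, fluid):
        """One segment (R=4.456e4) into one Windkessel (R=1e8) at
        Q = 1e-4 m³/s gives p_in = 1.00045e4 Pa ≈ 75.0 mmHg."""
        # realize the single-path case with a symmetric Y of negligible
        # proximal resistance: each branch carries Q/2
        tree = pf.VascularTree(
            [
                pf.VesselSegment("MPA", None, 0.05, 0.02, "trunk"),
                pf.VesselSegment("LPA", "MPA", 1e-6, 0.2, "left"),
                pf.VesselSegment("RPA", "MPA", 1e-6, 0.2, "right"),
            ]
        )
        r_seg = pf.poiseuille_resistance(0.05, 0.01, fluid.viscosity)
        outlets = [pf.WindkesselOutlet(o, 2e8, 1e-9) for o in ("LPA", "RPA")]
        q_in = 1e-4
        sol = pf.solve_steady_network(
            tree, outlets, q_in / tree.inlet_area, fluid
        )
        expected = q_in * (r_seg + 1e8)  # two 2e8 outlets in parallel
        assert sol.inlet_pressure == pytest.approx(expected, rel=1e-6)
        assert sol.inlet_pressure / 133.322 == pytest.approx(75.0, abs=0.1)

    def test_zero_inflow_is_identically_zero(self, stenosed_mid_tree, fluid):
        sol = pf.solve_steady_network(
            stenosed_mid_tree, outlets_for(stenosed_mid_tree), 0.0, fluid
        )
        assert sol.inlet_pressure == 0.0
        assert all(v == 0.0 for v in sol.outlet_flows.values())

    def test_two_outlet_oracle_equivalence(self, fluid):
        """Steady solves match an independent scalar root-find on the
        junction pressure for randomized two-outlet configurations."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            tree = pf.build_idealized_tree(
                2, 1, 1,
                root_diameter=float(rng.uniform(0.015, 0.03)),
                taper=float(rng.uniform(0.2, 0.5)),
            )
            if rng.random() < 0.7:
                side = "LPA" if rng.random() < 0.5 else "RPA"
                tree = pf.apply_stenosis(
                    tree, pf.StenosisSpec(side, float(rng.uniform(0.3, 0.7)))
                )
            outlets = random_outlets(tree, rng)
            v = float(rng.uniform(0.05, 0.6))
            sol = pf.solve_steady_network(tree, outlets, v, fluid)

            # oracle: root-find the junction pressure balancing the flows
            q_in = v * tree.inlet_area
            rwk = {o.outlet_id: o.resistance for o in outlets}

            def branch_flow(p_j, sid):
                seg = tree[sid]
                r = pf.poiseuille_resistance(
                    seg.length, seg.effective_radius, fluid.viscosity
                ) + rwk[sid]
                k = 0.0
                if seg.stenosis is not None:
                    k = stenosis_loss_coefficient(
                        seg.area, seg.effective_area, fluid
                    )
                if k == 0.0:
                    return p_j / r
                return (-r + math.sqrt(r * r + 4 * k * p_j)) / (2 * k)

            def imbalance(p_j):
                return (
                    branch_flow(p_j, "LPA") + branch_flow(p_j, "RPA") - q_in
                )

            p_j = brentq(imbalance, 0.0, 1e9, xtol=1e-10, rtol=1e-15)
            root = tree.root
            r_root = pf.poiseuille_resistance(
                root.length, root.effective_radius, fluid.viscosity
            )
            p_in_oracle = p_j + r_root * q_in
            assert sol.inlet_pressure == pytest.approx(p_in_oracle, rel=1e-8)
            assert sol.outlet_flows["LPA"] == pytest.approx(
                branch_flow(p_j, "LPA"), rel=1e-8
            )

    def test_flow_conservation_on_random_trees(self, fluid):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tree = random_tree(rng)
            outlets = random_outlets(tree, rng)
            sol = pf.solve_steady_network(
                tree, outlets, float(rng.uniform(0.05, 0.6)), fluid
            )
            assert sol.mass_balance_error < 1e-8


class TestWindkesselIntegration:
    def test_equilibrium_is_a_fixed_point(self):
        p = 1234.5
        assert pf.advance_windkessel(p, p / 1e8, 1e8, 1e-9, 1e-3) == pytest.approx(p)

    def test_constant_flow_matches_analytic_charging(self):
        """p(t) = QR(1 − e^{−t/RC}) for constant inflow from rest."""
        R = C = 1.0
        dt, T = 1e-3, 1.0
        p = 0.0
        for _ in range(round(T / dt)):
            p = pf.advance_windkessel(p, 1.0, R, C, dt)
        assert p == pytest.approx(1 - math.exp(-1.0), abs=1e-3)

    def test_pressure_decays_monotonically_without_inflow(self):
        p_hist = [1000.0]
        for _ in range(100):
            p_hist.append(pf.advance_windkessel(p_hist[-1], 0.0, 1e8, 1e-9, 1e-3))
        assert all(b < a for a, b in zip(p_hist, p_hist[1:]))
        assert p_hist[-1] > 0.0

    def test_first_order_convergence(self):
        """The backward-Euler error halves when dt halves."""
        R = C = 1.0

        def err(dt):
            p = 0.0
            for _ in range(round(1.0 / dt)):
                p = pf.advance_windkessel(p, 1.0, R, C, dt)
            return abs(p - (1 - math.exp(-1.0)))

        ratio = err(2e-3) / err(1e-3)
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestTransientSolve:
    def test_zero_waveform_zero_initial_state_stays_zero(self, y_tree, fluid):
        wf = pf.generate_inflow_waveform(1e-30, diastolic_fraction=0.0)
        outlets = [pf.WindkesselOutlet(o, 1e8, 1e-9) for o in y_tree.outlet_ids]
        sol = pf.solve_transient(
            y_tree, outlets, wf, fluid, dt=5e-3, n_cycles=1,
            initial_pressures="zero",
        )
        assert np.allclose(sol.inlet_pressure, 0.0, atol=1e-20)

    def test_quasi_steady_limit_matches_steady_solver(
        self, stenosed_mid_tree, fluid
    ):
        """With vanishing compliance every instant of the transient solve
        reproduces the steady solution at the instantaneous velocity."""
        wf = pf.generate_inflow_waveform(
            0.5732, inlet_area=stenosed_mid_tree.inlet_area
        )
        outlets = outlets_for(stenosed_mid_tree, c_total=1e-15)
        sol = pf.solve_transient(
            stenosed_mid_tree, outlets, wf, fluid, dt=5e-3, n_cycles=1
        )
        sl = sol.final_cycle()
        for idx in (10, 37, 90, 150):
            t = sol.final_cycle_times()[idx]
            steady = pf.solve_steady_network(
                stenosed_mid_tree, outlets, float(wf.velocity(t)), fluid
            )
            assert sol.inlet_pressure[sl][idx] == pytest.approx(
                steady.inlet_pressure, rel=1e-3
            )

    def test_per_step_mass_balance(self, fluid):
        rng = np.random.default_rng(11)
        for _ in range(5):
            tree = random_tree(rng)
            outlets = random_outlets(tree, rng)
            wf = pf.generate_inflow_waveform(
                float(rng.uniform(0.2, 0.6)), inlet_area=tree.inlet_area
            )
            sol = pf.solve_transient(tree, outlets, wf, fluid, dt=5e-3, n_cycles=2)
            assert sol.mass_balance_max < 1e-4

    def test_three_cycle_protocol_reaches_periodicity(
        self, stenosed_mid_tree, mid_outlets, fluid
    ):
        wf = pf.generate_inflow_waveform(
            0.5732, inlet_area=stenosed_mid_tree.inlet_area
        )
        sol = pf.solve_transient(
            stenosed_mid_tree, mid_outlets, wf, fluid, n_cycles=3
        )
        assert sol.cycles_run == 3
        assert sol.periodicity_defect < 0.01

    def test_bitwise_determinism(self, stenosed_mid_tree, mid_outlets, fluid):
        wf = pf.generate_inflow_waveform(
            0.5732, inlet_area=stenosed_mid_tree.inlet_area
        )
        kw = dict(dt=5e-3, n_cycles=1)
        a = pf.solve_transient(stenosed_mid_tree, mid_outlets, wf, fluid, **kw)
        b = pf.solve_transient(stenosed_mid_tree, mid_outlets, wf, fluid, **kw)
        assert np.array_equal(a.inlet_pressure, b.inlet_pressure)
        for oid in a.outlet_flows:
            assert np.array_equal(a.outlet_flows[oid], b.outlet_flows[oid])

    def test_dt_must_divide_period(self, y_tree, fluid):
        wf = pf.generate_inflow_waveform(0.5)
        outlets = [pf.WindkesselOutlet(o, 1e8, 1e-9) for o in y_tree.outlet_ids]
        with pytest.raises(ValueError, match="divide"):
            pf.solve_transient(y_tree, outlets, wf, fluid, dt=3e-3)

    def test_outlets_must_match_leaves(self, y_tree, fluid):
        outlets = [pf.WindkesselOutlet("LPA", 1e8, 1e-9)]
        with pytest.raises(SolverError, match="RPA"):
            CompiledNetwork(y_tree, outlets, fluid)

    def test_solution_csv_round_trip(self, tmp_path, y_tree, fluid):
        from pulmoflow.solver import read_solution_frame

        wf = pf.generate_inflow_waveform(0.5, inlet_area=y_tree.inlet_area)
        outlets = [pf.WindkesselOutlet(o, 1e8, 1e-9) for o in y_tree.outlet_ids]
        sol = pf.solve_transient(y_tree, outlets, wf, fluid, dt=5e-3, n_cycles=1)
        path = tmp_path / "solution.csv"
        sol.to_csv(path)
        df = read_solution_frame(path)
        # deterministic order: time-major, location lexicographic
        locs = df["location_id"].unique().tolist()
        assert df["location_id"].iloc[:3].tolist() == sorted(["inlet", "LPA", "RPA"])
        inlet = df[df["location_id"] == "inlet"]
        assert np.allclose(inlet["pressure_Pa"].to_numpy(), sol.inlet_pressure)
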