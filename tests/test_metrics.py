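"""Clinical metrics: gradient statistics, flow ratios, wall shear,
percent changes, and pre/post comparison — including every printed
pre/post arithmetic pair of the study this package models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulmoflow as pf
from pulmoflow.units import MMHG_TO_PA, pa_to_mmhg


def mk_series(values, period=0.925):
    """A gradient series over (0, period] from equally spaced values."""
    n = len(values)
    t = period * np.arange(1, n + 1) / n
    return t, np.asarray(values, dtype=float)


class TestGradientStatistics:
    def test_constant_series(self):
        t, dp = mk_series([500.0] * 100)
        c = pa_to_mmhg(500.0)
        assert pf.peak_systolic_pg(t, dp, 0.38) == pytest.approx(c)
        assert pf.mean_pg(t, dp, 0.925) == pytest.approx(c)
        assert pf.diastolic_pg(t, dp, 0.38, 0.925) == pytest.approx(c)

    def test_half_on_half_off_mean(self):
        n = 1000
        dp = np.where(np.arange(1, n + 1) <= n // 2, 200.0, 0.0)
        t, dp = mk_series(dp)
        assert pf.mean_pg(t, dp, 0.925) == pytest.approx(
            pa_to_mmhg(100.0), rel=5e-3
        )

    def test_linear_ramp_mean_is_half_amplitude(self):
        n = 2000
        t = 0.925 * np.arange(1, n + 1) / n
        dp = 400.0 * t / 0.925
        assert pf.mean_pg(t, dp, 0.925) == pytest.approx(
            pa_to_mmhg(200.0), rel=5e-3
        )

    def test_triangular_pulse_peak_in_systole(self):
        t, dp = mk_series(np.concatenate([np.linspace(0, 800, 300),
                                          np.linspace(800, 0, 625)]))
        assert pf.peak_systolic_pg(t, dp, 0.38) == pytest.approx(
            pa_to_mmhg(800.0), rel=1e-2
        )

    def test_diastolic_peak_warns_but_reports_systolic_max(self):
        n = 925
        t = 0.925 * np.arange(1, n + 1) / n
        dp = np.where(t <= 0.38, 100.0, 300.0)
        with pytest.warns(UserWarning, match="diastole"):
            peak = pf.peak_systolic_pg(t, dp, 0.38)
        assert peak == pytest.approx(pa_to_mmhg(100.0))

    def test_zero_diastole_gives_zero_dpg(self):
        n = 925
        t = 0.925 * np.arange(1, n + 1) / n
        dp = np.where(t <= 0.38, 100.0, 0.0)
        assert pf.diastolic_pg(t, dp, 0.38, 0.925) == pytest.approx(0.0, abs=0.2)

    def test_mean_between_min_and_max(self):
        rng = np.random.default_rng(5)
        t, dp = mk_series(rng.uniform(0, 1000, size=300))
        m = pf.mean_pg(t, dp, 0.925)
        assert pa_to_mmhg(dp.min()) <= m <= pa_to_mmhg(dp.max())

    def test_unit_conversion_commutes_with_the_statistics(self):
        rng = np.random.default_rng(8)
        t, dp = mk_series(rng.uniform(0, 2000, size=250))
        m_pa_then_convert = pf.mean_pg(t, dp, 0.925)
        # converting the series first and averaging in mmHg is identical
        m_convert_then_avg = pf.mean_pg(t, dp / MMHG_TO_PA, 0.925) * MMHG_TO_PA
        assert m_pa_then_convert == pytest.approx(m_convert_then_avg, rel=1e-12)


class TestGradientSeriesFromSolution:
    def test_outlets_at_inlet_pressure_give_zero_series(
        self, y_tree, fluid
    ):
        wf = pf.generate_inflow_waveform(1e-30, diastolic_fraction=0.0)
        outlets = [pf.WindkesselOutlet(o, 1e8, 1e-9) for o in y_tree.outlet_ids]
        sol = pf.solve_transient(
            y_tree, outlets, wf, fluid, dt=5e-3, n_cycles=1,
            initial_pressures="zero",
        )
        t, dp = pf.pressure_gradient_series(sol)
        assert np.allclose(dp, 0.0, atol=1e-18)

    def test_unweighted_mean_over_two_outlets(self, y_tree, fluid):
        """With outlets at p_in − a and p_in − b the series is (a+b)/2."""
        wf = pf.generate_inflow_waveform(0.5, inlet_area=y_tree.inlet_area)
        outlets = [
            pf.WindkesselOutlet("LPA", 1e8, 1e-10),
            pf.WindkesselOutlet("RPA", 3e8, 1e-10),
        ]
        sol = pf.solve_transient(y_tree, outlets, wf, fluid, dt=5e-3, n_cycles=2)
        t, dp = pf.pressure_gradient_series(sol)
        sl = sol.final_cycle()
        a = sol.inlet_pressure[sl] - sol.outlet_pressures["LPA"][sl]
        b = sol.inlet_pressure[sl] - sol.outlet_pressures["RPA"][sl]
        assert np.allclose(dp, (a + b) / 2, rtol=1e-12)


class TestFlowRatio:
    def test_symmetric_tree_ratio_is_one(self, y_tree, fluid):
        wf = pf.generate_inflow_waveform(0.5, inlet_area=y_tree.inlet_area)
        outlets = [pf.WindkesselOutlet(o, 1e8, 1e-9) for o in y_tree.outlet_ids]
        sol = pf.solve_transient(y_tree, outlets, wf, fluid, dt=5e-3, n_cycles=1)
        assert pf.flow_ratio_at_peak_systole(sol, "left", y_tree) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_printed_percentage_splits_convert_to_printed_ratios(self):
        """A 22/78 split is the ratio 0.28; 28/72 is 0.39 (both printed)."""
        assert 22 / 78 == pytest.approx(0.28, abs=0.005)
        assert 28 / 72 == pytest.approx(0.39, abs=0.005)


class TestWallShear:
    def test_hand_value(self):
        assert pf.segment_wss(1e-4, 0.005, 3.5e-3) == pytest.approx(
            3.565, rel=1e-3
        )

    def test_radius_scaling(self):
        tau1 = pf.segment_wss(1e-4, 0.004, 3.5e-3)
        tau2 = pf.segment_wss(1e-4, 0.002, 3.5e-3)
        assert tau2 / tau1 == pytest.approx(8.0)

    def test_zero_flow_gives_zero_shear(self):
        assert pf.segment_wss(0.0, 0.005, 3.5e-3) == 0.0


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            # peak systolic pressure-gradient reductions
            (25.16, 21.05, -16.3),
            (32.08, 18.77, -41.5),
            (61.02, 57.36, -6.0),
            (70.45, 57.36, -18.6),
            # mean pressure-gradient reductions
            (4.91, 4.09, -16.7),
            (5.71, 3.55, -37.8),
            (11.07, 10.31, -6.9),
            (12.44, 10.31, -17.1),
            # diastolic pressure-gradient reductions
            (4.73, 4.29, -9.3),
            (4.10, 3.41, -16.8),
            (8.63, 7.16, -17.0),
            (9.48, 7.16, -24.5),
            # flow-ratio increases
            (0.28, 0.39, 39.3),
            (0.39, 0.45, 15.4),
            (0.28, 0.45, 60.7),
        ],
    )
    def test_reproduces_printed_pre_post_arithmetic(self, pre, post, expected):
        assert round(pf.percent_change(pre, post), 1) == expected

    def test_flow_ratio_rounding_inconsistency_documented(self):
        """The published 8.2% change for the near-balanced case is not
        reproducible from its rounded ratios (0.86, 0.92 → 7.0%); the
        unrounded 46/54 → 48/52 splits give 8.4%."""
        assert round(pf.percent_change(0.86, 0.92), 1) == 7.0
        assert pf.percent_change(46 / 54, 48 / 52) == pytest.approx(8.36, abs=0.01)

    def test_identity_and_zero_pre(self):
        assert pf.percent_change(3.7, 3.7) == 0.0
        with pytest.raises(ValueError):
            pf.percent_change(0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pre=st.floats(0.1, 100), post=st.floats(0.1, 100)
    )
    def test_sign_convention(self, pre, post):
        pc = pf.percent_change(pre, post)
        assert (pc > 0) == (post > pre) or pc == 0
        # the formula is directional, not symmetric under role exchange
        back = pf.percent_change(post, pre)
        assert pc * back <= 0


class TestPrePostComparison:
    def mk_metrics(self, dpg, peak, mean, ratio):
        return pf.HemodynamicMetrics(
            peak_systolic_pg=peak, mean_pg=mean, dpg=dpg, flow_ratio=ratio
        )

    def test_percent_changes_for_every_scalar(self):
        pre = self.mk_metrics(4.73, 25.16, 4.91, 0.28)
        post = self.mk_metrics(4.29, 21.05, 4.09, 0.39)
        comp = pf.compare_pre_post(pre, post)
        assert round(comp.percent_changes["peak_systolic_pg"], 1) == -16.3
        assert round(comp.percent_changes["dpg"], 1) == -9.3
        assert round(comp.percent_changes["mean_pg"], 1) == -16.7
        assert round(comp.percent_changes["flow_ratio"], 1) == 39.3

    def test_identical_metrics_give_zero_changes(self):
        m = self.mk_metrics(4.0, 20.0, 5.0, 0.5)
        comp = pf.compare_pre_post(m, m)
        assert all(v == 0.0 for v in comp.percent_changes.values())

    def test_report_table_has_gradient_and_ratio_columns(self, tmp_path):
        import pandas as pd

        comp = pf.compare_pre_post(
            self.mk_metrics(8.63, 61.02, 11.07, 0.39),
            self.mk_metrics(7.16, 57.36, 10.31, 0.45),
        )
        path = tmp_path / "comparison.csv"
        comp.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "model", "dpg_mmHg", "peak_systolic_pg_mmHg",
            "mean_pg_mmHg", "flow_ratio",
        ]
        assert df.shape[0] == 3
        assert df.loc[2, "flow_ratio"] == pytest.approx(15.4)

    def test_dpg_remodeling_annotation(self):
        assert self.mk_metrics(9.48, 70.45, 12.44, 0.28).dpg_above_remodeling_threshold
        assert not self.mk_metrics(4.1, 32.08, 5.71, 0.86).dpg_above_remodeling_threshold
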