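"""Model/Results interface to the reduced-order hemodynamics machinery.

:class:`PulmonaryHemodynamicsModel` bundles the data of one study — a
vascular tree (possibly stenosed), an inlet waveform, fluid properties
and Windkessel boundary conditions. Its :meth:`fit` personalizes the
outlet resistances against a target flow ratio (or skips tuning when no
target applies) and runs the transient simulation; the returned
:class:`PulmonaryHemodynamicsResults` carries the tuned parameters, the
solution, the clinical metric bundle, convergence diagnostics, and a
``summary()`` table. Virtual surgery (stenosis removal) and the
parametric pressure-gradient shortcut hang off the results object.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Optional, Sequence


from . import metrics as _metrics
from . import parametric as _parametric
from . import tuning as _tuning
from .config import PipelineConfig
from .solver import (
    NetworkSolution,
    WindkesselOutlet,
    build_outlets,
    solve_transient,
)
from .tree import (
    FluidProperties,
    InflowWaveform,
    StenosisSpec,
    VascularTree,
    apply_stenosis,
    branch_area_ratio,
    build_idealized_tree,
    generate_inflow_waveform,
    remove_all_stenoses,
)

__all__ = ["PulmonaryHemodynamicsModel", "PulmonaryHemodynamicsResults"]


class PulmonaryHemodynamicsModel:
    """A patient-specific reduced-order pulmonary hemodynamics model.

    Parameters
    ----------
    tree : VascularTree
        Arterial morphology (with its stenosis, if any).
    waveform : InflowWaveform
        Periodic inlet velocity profile.
    outlets : sequence of WindkesselOutlet
        Terminal boundary conditions, one per tree leaf.
    fluid : FluidProperties
        Blood density and viscosity.
    stenosed_side : {"left", "right"}, optional
        Side carrying the stenosis; inferred from the tree when absent.
    dt, n_cycles, kt : solver settings (time step, cycles to periodic
        steady state, stenosis loss coefficient).
    """

    def __init__(
        self,
        tree: VascularTree,
        waveform: InflowWaveform,
        outlets: Sequence[WindkesselOutlet],
        fluid: FluidProperties = FluidProperties(),
        stenosed_side: Optional[str] = None,
        dt: float = 1e-3,
        n_cycles: int = 3,
        kt: float = 1.52,
    ):
        self.tree = tree
        self.waveform = waveform
        self.outlets = list(outlets)
        self.fluid = fluid
        self.dt = dt
        self.n_cycles = n_cycles
        self.kt = kt
        if stenosed_side is None:
            stenosed = tree.stenosed_segments()
            stenosed_side = stenosed[0].side if stenosed else "right"
        self.stenosed_side = stenosed_side

    # -- constructors -------------------------------------------------
    @classmethod
    def from_config(cls, config: PipelineConfig) -> "PulmonaryHemodynamicsModel":
        """Build tree, waveform and outlets from a validated configuration."""
        tc = config.tree
        tree = build_idealized_tree(
            generations=tc.generations,
            left_outlets=tc.left_outlets,
            right_outlets=tc.right_outlets,
            root_diameter=tc.root_diameter,
            taper=tc.taper,
            length_ratio=tc.length_ratio,
        )
        stenosed_side = None
        if config.stenosis is not None:
            spec = StenosisSpec(
                segment_id=config.stenosis.segment_id,
                diameter_reduction=config.stenosis.diameter_reduction,
            )
            tree = apply_stenosis(tree, spec)
            stenosed_side = tree[spec.segment_id].side
        wc = config.waveform
        waveform = generate_inflow_waveform(
            peak_velocity=wc.peak_velocity,
            period=wc.period,
            systole_end=wc.systole_end,
            diastolic_fraction=wc.diastolic_fraction,
            n_samples=wc.n_samples,
            inlet_area=wc.inlet_area if wc.inlet_area is not None else tree.inlet_area,
        )
        fluid = FluidProperties(
            density=config.fluid.density, viscosity=config.fluid.viscosity
        )
        outlets = build_outlets(
            tree,
            left_resistance=config.windkessel.left_resistance,
            right_resistance=config.windkessel.right_resistance,
            total_compliance=config.windkessel.compliance(),
        )
        return cls(
            tree=tree,
            waveform=waveform,
            outlets=outlets,
            fluid=fluid,
            stenosed_side=stenosed_side,
            dt=config.solver.dt,
            n_cycles=config.solver.n_cycles,
            kt=config.solver.kt,
        )

    # -- core ---------------------------------------------------------
    def size_ratio(self, method: str = "proximal") -> float:
        """Stenosed-over-non-stenosed branch area ratio of this morphology."""
        return branch_area_ratio(self.tree, self.stenosed_side, method=method)

    def simulate(
        self, outlets: Optional[Sequence[WindkesselOutlet]] = None
    ) -> NetworkSolution:
        """Run the transient solve with the model's (or given) outlets."""
        return solve_transient(
            self.tree,
            self.outlets if outlets is None else outlets,
            self.waveform,
            self.fluid,
            dt=self.dt,
            n_cycles=self.n_cycles,
            kt=self.kt,
        )

    def fit(
        self,
        target_flow_ratio: Optional[float] = None,
        flow_size_curve: Optional[_tuning.FlowSizeCurve] = None,
        tune: bool = True,
        tolerance: float = 0.01,
        tuning_mode: str = "transient",
        size_ratio_method: str = "proximal",
    ) -> "PulmonaryHemodynamicsResults":
        """Personalize the boundary conditions and run the simulation.

        When ``tune`` is true the stenosed branch's resistances are
        swept to the target flow ratio; if no explicit target is given
        it is derived from the size ratio through the flow-size curve
        (default exponent β = 0.9). With ``tune=False`` the outlets are
        used as supplied.
        """
        tuning_report = None
        outlets = [dataclasses.replace(o) for o in self.outlets]
        if tune:
            if target_flow_ratio is None:
                curve = flow_size_curve or _tuning.FlowSizeCurve(_tuning.DEFAULT_BETA)
                target_flow_ratio = _tuning.expected_flow_ratio(
                    curve, self.size_ratio(method=size_ratio_method)
                )
            outlets, tuning_report = _tuning.sweep_stenosed_resistance(
                self.tree,
                outlets,
                self.waveform,
                target_flow_ratio=target_flow_ratio,
                stenosed_side=self.stenosed_side,
                fluid=self.fluid,
                tolerance=tolerance,
                mode=tuning_mode,
                dt=self.dt,
                n_cycles=self.n_cycles,
                kt=self.kt,
            )
        solution = self.simulate(outlets)
        metric_bundle = _metrics.compute_metrics(
            solution, self.tree, self.stenosed_side, self.fluid
        )
        return PulmonaryHemodynamicsResults(
            model=self,
            outlets=list(outlets),
            solution=solution,
            metrics=metric_bundle,
            tuning_report=tuning_report,
        )

    def without_stenosis(self) -> "PulmonaryHemodynamicsModel":
        """The virtual-surgery counterpart: same model, stenoses removed."""
        return PulmonaryHemodynamicsModel(
            tree=remove_all_stenoses(self.tree),
            waveform=self.waveform,
            outlets=[dataclasses.replace(o) for o in self.outlets],
            fluid=self.fluid,
            stenosed_side=self.stenosed_side,
            dt=self.dt,
            n_cycles=self.n_cycles,
            kt=self.kt,
        )


@dataclass
class PulmonaryHemodynamicsResults:
    """Fitted boundary conditions, simulation output and clinical metrics."""

    model: PulmonaryHemodynamicsModel
    outlets: list[WindkesselOutlet]
    solution: NetworkSolution
    metrics: _metrics.HemodynamicMetrics
    tuning_report: Optional[_tuning.TuningReport] = None

    # -- derived ------------------------------------------------------
    @property
    def diagnostics(self) -> dict:
        d = {
            "mass_balance_max_rel_error": self.solution.mass_balance_max,
            "periodicity_defect": self.solution.periodicity_defect,
            "cycles_run": self.solution.cycles_run,
        }
        if self.tuning_report is not None:
            tr = self.tuning_report
            d.update(
                tuning_target_flow_ratio=tr.target_flow_ratio,
                tuning_achieved_flow_ratio=tr.achieved_flow_ratio,
                tuning_resistance_scale=tr.resistance_scale,
                tuning_iterations=tr.iterations,
            )
        return d

    def pressure_gradient(self) -> _parametric.GradientSeries:
        """Final-cycle Δp(t) of the transient solution (Pa)."""
        t, dp = _metrics.pressure_gradient_series(self.solution)
        return _parametric.GradientSeries(times=t, dp=dp)

    def parametric_fit(
        self,
        fractions: Sequence[float] = (0.25, 0.5, 1.0),
        constrain_origin: bool = True,
    ) -> _parametric.ParametricFit:
        """Constant-flow series + quadratic fit for this morphology."""
        v_max = self.model.waveform.peak_velocity
        pts = _parametric.run_constant_flow_series(
            self.model.tree,
            self.outlets,
            v_max,
            self.model.fluid,
            fractions=fractions,
            inlet_area=self.model.waveform.inlet_area,
            kt=self.model.kt,
        )
        return _parametric.fit_quadratic(pts, v_max, constrain_origin=constrain_origin)

    def predict_pressure_gradient(
        self, fit: Optional[_parametric.ParametricFit] = None
    ) -> _parametric.GradientSeries:
        """Parametric Δp(t) prediction on the final-cycle time grid."""
        if fit is None:
            fit = self.parametric_fit()
        times = self.solution.final_cycle_times()
        return _parametric.predict_transient_gradient(
            fit, self.model.waveform, times=times
        )

    def virtual_surgery(self) -> "PulmonaryHemodynamicsResults":
        """Re-simulate with the stenosis removed, keeping the tuned outlets."""
        repaired = self.model.without_stenosis()
        repaired.outlets = [dataclasses.replace(o) for o in self.outlets]
        return repaired.fit(tune=False)

    def compare_with(
        self, post: "PulmonaryHemodynamicsResults"
    ) -> _metrics.PrePostComparison:
        """Pre/post comparison: this result as 'pre', the argument as 'post'."""
        return _metrics.compare_pre_post(self.metrics, post.metrics)

    # -- presentation -------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of boundary conditions, metrics, diagnostics."""
        m = self.metrics
        buf = io.StringIO()
        w = buf.write
        w("Pulmonary hemodynamics (reduced-order network model)\n")
        w("=" * 56 + "\n")
        tree = self.model.tree
        sten = tree.stenosed_segments()
        w(f"Segments: {tree.n_segments}   Outlets: {len(tree.outlet_ids)} "
          f"({len(tree.outlet_ids_on_side('left'))} left / "
          f"{len(tree.outlet_ids_on_side('right'))} right)\n")
        if sten:
            s = sten[0]
            w(f"Stenosis: {s.id} ({s.side}), diameter reduction "
              f"{100 * s.stenosis:.1f}%\n")
        else:
            w("Stenosis: none\n")
        if self.tuning_report is not None:
            tr = self.tuning_report
            w(f"Tuning:   target flow ratio {tr.target_flow_ratio:.4f}, achieved "
              f"{tr.achieved_flow_ratio:.4f} (resistance scale "
              f"{tr.resistance_scale:.4g}, {tr.iterations} evaluations)\n")
        w("-" * 56 + "\n")
        w(f"{'Peak systolic PG':26s} {m.peak_systolic_pg:10.2f} mmHg\n")
        w(f"{'Mean PG':26s} {m.mean_pg:10.2f} mmHg\n")
        w(f"{'DPG (diastolic mean)':26s} {m.dpg:10.2f} mmHg")
        if m.dpg_above_remodeling_threshold:
            w("   [> 7 mmHg]")
        w("\n")
        w(f"{'Flow ratio @ peak systole':26s} {m.flow_ratio:10.2f}\n")
        w("-" * 56 + "\n")
        d = self.diagnostics
        w(f"mass balance max rel. error  {d['mass_balance_max_rel_error']:.2e}\n")
        w(f"periodicity defect           {d['periodicity_defect']:.2e}\n")
        return buf.getvalue()

    def plot_pressure_gradient(self, ax=None, include_parametric: bool = False):
        """Plot the final-cycle Δp(t) (and optionally its parametric prediction)."""
        import matplotlib.pyplot as plt

        from .units import pa_to_mmhg

        if ax is None:
            _, ax = plt.subplots()
        g = self.pressure_gradient()
        ax.plot(g.times, pa_to_mmhg(g.dp), label="transient")
        if include_parametric:
            p = self.predict_pressure_gradient()
            ax.plot(p.times, pa_to_mmhg(p.dp), "--", label="parametric")
        ax.set_xlabel("time in cycle (s)")
        ax.set_ylabel("inlet-to-outlet pressure gradient (mmHg)")
        ax.legend()
        return ax
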