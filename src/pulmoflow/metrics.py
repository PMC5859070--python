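"""Clinical hemodynamic metrics and pre/post virtual-surgery comparison.

The quantities computed here are the ones surgeons look at when judging
whether removing a proximal pulmonary obstruction will pay off:

* the inlet-to-outlet pressure gradient over the cardiac cycle, and its
  peak systolic value, cycle mean, and diastolic mean (DPG analog);
* the flow ratio between the stenosed and the non-stenosed pulmonary
  artery at peak systole;
* a Poiseuille wall-shear estimate per segment;
* percent changes of all of the above between the stenosed and the
  repaired morphology.

Pressure gradients are defined as inlet pressure minus the unweighted
mean of the outlet pressures (a flow-weighted variant is available).
The clinical DPG uses the wedge pressure, which has no analog in this
model; the diastolic-interval time-average of the inlet-to-outlet
gradient is used as its simulation counterpart. Internally everything
is Pa; reported metrics are in mmHg.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np

from .solver import NetworkSolution
from .tree import FluidProperties, VascularTree
from .units import pa_to_mmhg

__all__ = [
    "HemodynamicMetrics",
    "PrePostComparison",
    "pressure_gradient_series",
    "peak_systolic_pg",
    "mean_pg",
    "diastolic_pg",
    "flow_ratio_at_peak_systole",
    "segment_wss",
    "percent_change",
    "compute_metrics",
    "compare_pre_post",
]

DPG_REMODELING_THRESHOLD_MMHG = 7.0  # reported as an annotation only


def pressure_gradient_series(
    solution: NetworkSolution, weighting: str = "unweighted"
) -> tuple[np.ndarray, np.ndarray]:
    """Δp(t) over the final cycle: inlet minus (mean) outlet pressure, in Pa.

    Returns ``(times, dp)`` with times rebased to (0, period]. The
    default averages outlet pressures without weights; ``"flow"``
    weights each outlet by its instantaneous flow magnitude.
    """
    if solution.cycles_run < 1 or len(solution.times) < solution.steps_per_cycle:
        raise ValueError("solution does not contain a complete cycle")
    sl = solution.final_cycle()
    t = solution.final_cycle_times()
    p_in = solution.inlet_pressure[sl]
    out = np.array([p[sl] for p in solution.outlet_pressures.values()])
    if weighting == "unweighted":
        p_out = out.mean(axis=0)
    elif weighting == "flow":
        w = np.abs(np.array([q[sl] for q in solution.outlet_flows.values()]))
        wsum = w.sum(axis=0)
        wsum[wsum == 0] = np.nan
        p_out = (out * w).sum(axis=0) / wsum
        p_out = np.where(np.isnan(p_out), out.mean(axis=0), p_out)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return t, p_in - p_out


def _wrap_cycle(times: np.ndarray, dp: np.ndarray, period: float):
    """Prepend the periodic t=0 point (equal to the t=period sample)."""
    t = np.concatenate(([0.0], times))
    y = np.concatenate(([dp[-1]], dp))
    if abs(t[-1] - period) > 1e-9 * period:
        raise ValueError("gradient series does not span one full period")
    return t, y


def peak_systolic_pg(times: np.ndarray, dp: np.ndarray, systole_end: float) -> float:
    """Maximum of Δp over the systolic interval [0, systole_end], in mmHg.

    If the cycle-wide maximum falls in diastole a warning is issued and
    the systolic maximum is still returned.
    """
    times = np.asarray(times, float)
    dp = np.asarray(dp, float)
    sys_mask = times <= systole_end + 1e-12
    if not sys_mask.any():
        raise ValueError("no samples in the systolic interval")
    peak_sys = float(dp[sys_mask].max())
    if dp.max() > peak_sys:
        warnings.warn(
            "pressure gradient peaks in diastole; reporting the systolic maximum",
            stacklevel=2,
        )
    return float(pa_to_mmhg(peak_sys))


def mean_pg(times: np.ndarray, dp: np.ndarray, period: float) -> float:
    """Trapezoidal time-average of Δp over the full final cycle, in mmHg."""
    t, y = _wrap_cycle(np.asarray(times, float), np.asarray(dp, float), period)
    return float(pa_to_mmhg(np.trapezoid(y, t) / period))


def diastolic_pg(
    times: np.ndarray, dp: np.ndarray, systole_end: float, period: float
) -> float:
    """Diastolic-interval time-average of Δp (the model's DPG analog), in mmHg."""
    times = np.asarray(times, float)
    dp = np.asarray(dp, float)
    mask = times >= systole_end - 1e-12
    t = times[mask]
    y = dp[mask]
    if t.size < 2:
        raise ValueError("no samples in the diastolic interval")
    return float(pa_to_mmhg(np.trapezoid(y, t) / (t[-1] - t[0])))


def flow_ratio_at_peak_systole(
    solution: NetworkSolution, stenosed_side: str, tree: VascularTree
) -> float:
    """Stenosed-side over non-stenosed-side outlet flow at peak inlet flow.

    Both sums are taken at the time step of maximum inlet flow within
    the final cycle.
    """
    if stenosed_side not in ("left", "right"):
        raise ValueError("stenosed_side must be 'left' or 'right'")
    other = "right" if stenosed_side == "left" else "left"
    sl = solution.final_cycle()
    offset = sl.start if sl.start is not None else 0
    idx = offset + int(np.argmax(solution.inlet_flow[sl]))
    q_sten = sum(
        solution.outlet_flows[o][idx] for o in tree.outlet_ids_on_side(stenosed_side)
    )
    q_non = sum(
        solution.outlet_flows[o][idx] for o in tree.outlet_ids_on_side(other)
    )
    return float(q_sten / q_non)


def segment_wss(flow: float, radius: float, viscosity: float) -> float:
    """Poiseuille wall shear magnitude τ = 4·μ·|Q|/(π·r³), in Pa."""
    if not (radius > 0 and viscosity > 0):
        raise ValueError("radius and viscosity must be > 0")
    return 4.0 * viscosity * abs(flow) / (math.pi * radius**3)


def percent_change(pre: float, post: float) -> float:
    """Signed percent change 100·(post − pre)/pre.

    Full precision is kept; round only at presentation.
    """
    if pre == 0:
        raise ValueError("percent_change undefined for pre == 0")
    return 100.0 * (post - pre) / pre


# ---------------------------------------------------------------------
# metric bundles
# ---------------------------------------------------------------------

@dataclass
class HemodynamicMetrics:
    """All scalar metrics of one simulation (pressures in mmHg)."""

    peak_systolic_pg: float
    mean_pg: float
    dpg: float
    flow_ratio: float
    per_segment_wss: dict[str, float] = field(default_factory=dict)
    per_branch_flows: dict[str, float] = field(default_factory=dict)

    SCALARS = ("dpg", "peak_systolic_pg", "mean_pg", "flow_ratio")

    def __post_init__(self) -> None:
        for name in self.SCALARS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"metric {name} is not finite: {v}")
        if not (self.flow_ratio > 0):
            raise ValueError(f"flow_ratio must be > 0, got {self.flow_ratio}")

    @property
    def dpg_above_remodeling_threshold(self) -> bool:
        """Annotation: DPG above the 7 mmHg distal-remodeling flag."""
        return self.dpg > DPG_REMODELING_THRESHOLD_MMHG

    def as_dict(self) -> dict:
        return {
            "dpg_mmHg": self.dpg,
            "peak_systolic_pg_mmHg": self.peak_systolic_pg,
            "mean_pg_mmHg": self.mean_pg,
            "flow_ratio": self.flow_ratio,
            "dpg_above_remodeling_threshold": self.dpg_above_remodeling_threshold,
            "per_segment_wss_Pa": self.per_segment_wss,
            "per_branch_flows_m3s": self.per_branch_flows,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def compute_metrics(
    solution: NetworkSolution,
    tree: VascularTree,
    stenosed_side: str,
    fluid: FluidProperties,
    weighting: str = "unweighted",
) -> HemodynamicMetrics:
    """Compute the full metric bundle from a transient solution.

    Wall shear is evaluated per segment from the flow at peak systole of
    the final cycle using the effective (stenotic where narrowed)
    radius.
    """
    t, dp = pressure_gradient_series(solution, weighting=weighting)
    sl = solution.final_cycle()
    offset = sl.start if sl.start is not None else 0
    idx = offset + int(np.argmax(solution.inlet_flow[sl]))
    wss = {}
    for sid, q in solution.segment_flows.items():
        wss[sid] = segment_wss(
            float(q[idx]), tree[sid].effective_radius, fluid.viscosity
        )
    branch_flows = {
        side: float(
            sum(solution.outlet_flows[o][idx] for o in tree.outlet_ids_on_side(side))
        )
        for side in ("left", "right")
    }
    return HemodynamicMetrics(
        peak_systolic_pg=peak_systolic_pg(t, dp, solution.systole_end),
        mean_pg=mean_pg(t, dp, solution.period),
        dpg=diastolic_pg(t, dp, solution.systole_end, solution.period),
        flow_ratio=flow_ratio_at_peak_systole(solution, stenosed_side, tree),
        per_segment_wss=wss,
        per_branch_flows=branch_flows,
    )


@dataclass
class PrePostComparison:
    """Paired metrics before/after stenosis removal with percent changes."""

    pre: HemodynamicMetrics
    post: HemodynamicMetrics
    percent_changes: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.percent_changes = {
            name: percent_change(getattr(self.pre, name), getattr(self.post, name))
            for name in HemodynamicMetrics.SCALARS
        }

    def as_dict(self) -> dict:
        return {
            "stenosed": self.pre.as_dict(),
            "non_stenosed": self.post.as_dict(),
            "percent_changes": self.percent_changes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def to_frame(self):
        """Flat table: one row per morphology plus a percent-change row."""
        import pandas as pd

        rows = []
        for label, m in (("stenosed", self.pre), ("non_stenosed", self.post)):
            rows.append(
                {
                    "model": label,
                    "dpg_mmHg": round(m.dpg, 2),
                    "peak_systolic_pg_mmHg": round(m.peak_systolic_pg, 2),
                    "mean_pg_mmHg": round(m.mean_pg, 2),
                    "flow_ratio": round(m.flow_ratio, 2),
                }
            )
        pc = self.percent_changes
        rows.append(
            {
                "model": "percent_change",
                "dpg_mmHg": round(pc["dpg"], 1),
                "peak_systolic_pg_mmHg": round(pc["peak_systolic_pg"], 1),
                "mean_pg_mmHg": round(pc["mean_pg"], 1),
                "flow_ratio": round(pc["flow_ratio"], 1),
            }
        )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_pre_post(
    stenosed_metrics: HemodynamicMetrics, nonstenosed_metrics: HemodynamicMetrics
) -> PrePostComparison:
    """Package pre/post metric sets with percent changes for every scalar."""
    return PrePostComparison(pre=stenosed_metrics, post=nonstenosed_metrics)
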