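"""Personalization of the Windkessel boundary conditions.

The multi-step procedure mirrors how clinical flow-split measurements
are used to set outlet resistances when no catheter data is available:

1. an exponential flow-split-versus-size-ratio curve, calibrated on
   published branch-pulmonary-stenosis measurements, maps the patient's
   left/right size ratio to an expected flow ratio;
2. the resistances of the stenosed branch are swept (a bisection on a
   log-scale multiplier, justified by the monotone ratio-resistance
   relation) until the simulated peak-systolic flow ratio hits that
   target, with compliances held fixed;
3. the total compliance itself is estimated as stroke volume over pulse
   pressure.

The default curve exponent β = 0.9 is a stand-in constant of plausible
physiological magnitude, not a published fit; supply calibration points
via :func:`fit_flow_size_curve` to use real data.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import flow_ratio_at_peak_systole
from .solver import WindkesselOutlet, solve_steady_network, solve_transient
from .tree import FluidProperties, InflowWaveform, VascularTree

__all__ = [
    "FlowSizeCurve",
    "TuningReport",
    "TuningError",
    "fit_flow_size_curve",
    "expected_flow_ratio",
    "estimate_compliance",
    "sweep_stenosed_resistance",
    "DEFAULT_BETA",
]

DEFAULT_BETA = 0.9


class TuningError(RuntimeError):
    """Raised when calibration or the resistance sweep cannot proceed."""


@dataclass(frozen=True)
class FlowSizeCurve:
    """Exponential flow-ratio vs size-ratio relation f(s) = exp(β·(s − 1)).

    The constrained form guarantees f(1) = 1 — equal branch areas give
    equal flows — and is monotone increasing for β > 0.
    """

    beta: float
    calibration_points: tuple[tuple[float, float], ...] = ()

    def __call__(self, size_ratio) -> float:
        s = np.asarray(size_ratio, dtype=float)
        if np.any(s <= 0):
            raise ValueError("size_ratio must be > 0")
        out = np.exp(self.beta * (s - 1.0))
        return float(out) if out.ndim == 0 else out


def fit_flow_size_curve(points: Sequence[tuple[float, float]]) -> FlowSizeCurve:
    """Least-squares fit of f(s) = exp(β·(s − 1)) to (size, flow) ratio pairs.

    The fit is the log-linear regression through the constrained point
    f(1) = 1: β = Σ x·ln(f) / Σ x² with x = s − 1. Points at s = 1 carry
    no information and a set of only such points is degenerate.
    """
    pts = [(float(s), float(f)) for s, f in points]
    if len(pts) < 2:
        raise TuningError("need at least two calibration points")
    if any(s <= 0 for s, _ in pts) or any(f <= 0 for _, f in pts):
        raise TuningError("size and flow ratios must be > 0")
    x = np.array([s - 1.0 for s, _ in pts])
    y = np.log([f for _, f in pts])
    sxx = float(np.dot(x, x))
    if sxx < 1e-24:
        raise TuningError(
            "degenerate calibration points: all size ratios equal 1; "
            "the exponent is unidentifiable"
        )
    beta = float(np.dot(x, y) / sxx)
    return FlowSizeCurve(beta=beta, calibration_points=tuple(pts))


def expected_flow_ratio(curve: FlowSizeCurve, size_ratio: float) -> float:
    """Evaluate the fitted curve at the patient's size ratio."""
    return curve(size_ratio)


def estimate_compliance(stroke_volume: float, pulse_pressure: float) -> float:
    """Total vessel compliance as stroke volume / pulse pressure (m³/Pa)."""
    if not (stroke_volume > 0):
        raise ValueError(f"stroke_volume must be > 0, got {stroke_volume}")
    if not (pulse_pressure > 0):
        raise ValueError(f"pulse_pressure must be > 0, got {pulse_pressure}")
    return stroke_volume / pulse_pressure


# ---------------------------------------------------------------------
# resistance sweep
# ---------------------------------------------------------------------

@dataclass
class TuningReport:
    """Outcome of a resistance sweep."""

    target_flow_ratio: float
    achieved_flow_ratio: float
    resistance_scale: float
    iterations: int
    evaluations: tuple[tuple[float, float], ...]  # (scale, ratio) pairs
    outlet_resistances: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "target_flow_ratio": self.target_flow_ratio,
            "achieved_flow_ratio": self.achieved_flow_ratio,
            "resistance_scale": self.resistance_scale,
            "iterations": self.iterations,
            "evaluations": [list(e) for e in self.evaluations],
            "outlet_resistances_Pa_s_per_m3": self.outlet_resistances,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def _scaled_outlets(
    outlets: Sequence[WindkesselOutlet],
    side_ids: set[str],
    scale: float,
) -> list[WindkesselOutlet]:
    return [
        dataclasses.replace(o, resistance=o.resistance * scale)
        if o.outlet_id in side_ids
        else dataclasses.replace(o)
        for o in outlets
    ]


def sweep_stenosed_resistance(
    tree: VascularTree,
    outlets: Sequence[WindkesselOutlet],
    waveform: InflowWaveform,
    target_flow_ratio: float,
    stenosed_side: str,
    fluid: FluidProperties,
    tolerance: float = 0.01,
    mode: str = "transient",
    dt: float = 1e-3,
    n_cycles: int = 3,
    kt: float = 1.52,
    bracket: tuple[float, float] = (1e-2, 1e2),
    max_bisections: int = 60,
) -> tuple[list[WindkesselOutlet], TuningReport]:
    """Scale the stenosed branch's outlet resistances to hit a flow ratio.

    A uniform multiplier on the stenosed-side resistances is bisected on
    a log scale over ``bracket`` until the simulated peak-systolic flow
    ratio is within ``tolerance`` (relative) of the target; compliances
    are untouched. The ratio is strictly decreasing in the multiplier,
    which is checked on the evaluations of every run.

    ``mode="transient"`` (default) measures the ratio at peak systole of
    the final cycle of a full transient solve, the same quantity the
    reported flow ratios use. ``mode="steady"`` is a cheaper flagged
    alternative using a steady solve at peak velocity.
    """
    if not (target_flow_ratio > 0):
        raise TuningError("target_flow_ratio must be > 0")
    if stenosed_side not in ("left", "right"):
        raise TuningError("stenosed_side must be 'left' or 'right'")
    if mode not in ("transient", "steady"):
        raise TuningError(f"unknown tuning mode {mode!r}")
    side_ids = set(tree.outlet_ids_on_side(stenosed_side))
    other = "right" if stenosed_side == "left" else "left"
    other_ids = tree.outlet_ids_on_side(other)

    def ratio_at(scale: float) -> float:
        cand = _scaled_outlets(outlets, side_ids, scale)
        if mode == "transient":
            sol = solve_transient(
                tree, cand, waveform, fluid, dt=dt, n_cycles=n_cycles, kt=kt
            )
            return flow_ratio_at_peak_systole(sol, stenosed_side, tree)
        sol = solve_steady_network(
            tree, cand, waveform.peak_velocity, fluid,
            inlet_area=waveform.inlet_area, kt=kt,
        )
        q_sten = sum(sol.outlet_flows[o] for o in side_ids)
        q_non = sum(sol.outlet_flows[o] for o in other_ids)
        return q_sten / q_non

    evals: list[tuple[float, float]] = []

    def measure(scale: float) -> float:
        r = ratio_at(scale)
        evals.append((scale, r))
        return r

    def done(r: float) -> bool:
        return abs(r - target_flow_ratio) / target_flow_ratio <= tolerance

    r1 = measure(1.0)
    if done(r1):
        tuned = _scaled_outlets(outlets, side_ids, 1.0)
        return tuned, _report(1.0, r1, target_flow_ratio, evals, tuned)

    lo, hi = bracket
    r_lo = measure(lo)   # small resistance -> large ratio
    r_hi = measure(hi)   # large resistance -> small ratio
    if not (min(r_lo, r_hi) <= target_flow_ratio <= max(r_lo, r_hi)):
        raise TuningError(
            f"target flow ratio {target_flow_ratio:.4g} outside the achievable "
            f"bracket [{min(r_lo, r_hi):.4g}, {max(r_lo, r_hi):.4g}] for "
            f"resistance scales in [{lo:.3g}, {hi:.3g}]"
        )
    a, b = math.log(lo), math.log(hi)
    ra, rb = r_lo, r_hi
    scale, r = 1.0, r1
    # the untuned point refines the bracket when it straddles the target
    if (ra - target_flow_ratio) * (r1 - target_flow_ratio) < 0:
        b, rb = 0.0, r1
    elif (rb - target_flow_ratio) * (r1 - target_flow_ratio) < 0:
        a, ra = 0.0, r1
    for it in range(1, max_bisections + 1):
        m = 0.5 * (a + b)
        scale = math.exp(m)
        r = measure(scale)
        if done(r):
            break
        if (ra - target_flow_ratio) * (r - target_flow_ratio) < 0:
            b, rb = m, r
        else:
            a, ra = m, r
    else:
        raise TuningError(
            f"sweep did not reach |ratio - target|/target <= {tolerance} in "
            f"{max_bisections} bisections (last ratio {r:.5g})"
        )
    _check_monotone(evals)
    tuned = _scaled_outlets(outlets, side_ids, scale)
    return tuned, _report(scale, r, target_flow_ratio, evals, tuned)


def _check_monotone(evals: list[tuple[float, float]]) -> None:
    """Warn if the ratio is not decreasing in the resistance scale."""
    pts = sorted(evals)
    for (s1, r1), (s2, r2) in zip(pts, pts[1:]):
        if r2 > r1 * (1.0 + 1e-9):
            warnings.warn(
                f"flow ratio not monotone in resistance scale near scale "
                f"{s2:.4g}: {r1:.6g} -> {r2:.6g}",
                stacklevel=3,
            )
            return


def _report(scale, achieved, target, evals, tuned) -> TuningReport:
    return TuningReport(
        target_flow_ratio=target,
        achieved_flow_ratio=achieved,
        resistance_scale=scale,
        iterations=len(evals),
        evaluations=tuple(evals),
        outlet_resistances={o.outlet_id: o.resistance for o in tuned},
    )
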