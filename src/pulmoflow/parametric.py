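"""Parametric (constant-flow) estimation of the transient pressure gradient.

Full transient simulations are the expensive part of a patient-specific
workflow. The parametric shortcut runs a handful of independent
constant-velocity steady solves (defaults: 0.25, 0.5 and 1.0 times the
peak inlet velocity), fits a degree-2 polynomial to the resulting
(normalized velocity, Δp) points, and predicts the transient gradient
by substituting the time-varying inflow velocity into the fitted
polynomial — no time-marching required. Error metrics against a full
transient solve quantify what the shortcut gives up.

By default the quadratic is constrained through the origin (zero flow
produces zero gradient in a rigid resistive network); the unconstrained
3-point interpolation is available via ``constrain_origin=False``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .solver import SolverError, WindkesselOutlet, solve_steady_network
from .tree import FluidProperties, InflowWaveform, VascularTree
from .units import pa_to_mmhg

__all__ = [
    "ParametricFit",
    "GradientSeries",
    "ErrorMetrics",
    "run_constant_flow_series",
    "fit_quadratic",
    "predict_transient_gradient",
    "parametric_error_metrics",
]

EXTRAPOLATION_SLACK = 0.05  # tolerated fraction above the calibrated v_max


@dataclass(frozen=True)
class ParametricFit:
    """Quadratic Δp = c₀ + c₁·υₙ + c₂·υₙ² in normalized velocity υₙ = υ/υ_max.

    Coefficients are in Pa. With three distinct points and no origin
    constraint the fit interpolates them exactly.
    """

    c0: float
    c1: float
    c2: float
    v_max: float
    fit_points: tuple[tuple[float, float], ...]
    constrained_origin: bool = True

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.c0, self.c1, self.c2)

    def __call__(self, v_n):
        v = np.asarray(v_n, dtype=float)
        out = self.c0 + self.c1 * v + self.c2 * v * v
        return float(out) if out.ndim == 0 else out

    def as_dict(self) -> dict:
        return {
            "coefficients_Pa": [self.c0, self.c1, self.c2],
            "v_max_m_per_s": self.v_max,
            "fit_points": [list(p) for p in self.fit_points],
            "constrained_origin": self.constrained_origin,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParametricFit":
        d = json.loads(Path(path).read_text())
        c0, c1, c2 = d["coefficients_Pa"]
        return cls(
            c0=c0, c1=c1, c2=c2, v_max=d["v_max_m_per_s"],
            fit_points=tuple(tuple(p) for p in d["fit_points"]),
            constrained_origin=d["constrained_origin"],
        )


@dataclass(frozen=True)
class GradientSeries:
    """A Δp(t) time series in Pa with an extrapolation flag."""

    times: np.ndarray
    dp: np.ndarray
    extrapolated: bool = False

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "dp_Pa", "dp_mmHg"])
            for t, p in zip(self.times, self.dp):
                w.writerow([repr(float(t)), repr(float(p)), repr(float(pa_to_mmhg(p)))])


def run_constant_flow_series(
    tree: VascularTree,
    outlets: Sequence[WindkesselOutlet],
    v_max: float,
    fluid: FluidProperties,
    fractions: Sequence[float] = (0.25, 0.5, 1.0),
    inlet_area: float | None = None,
    kt: float = 1.52,
) -> list[tuple[float, float]]:
    """One steady solve per velocity fraction; returns (υₙ, Δp) pairs.

    Δp is inlet pressure minus the unweighted mean outlet pressure. The
    solves are independent of each other, so results do not depend on
    execution order.
    """
    fr = [float(f) for f in fractions]
    if any(not (0.0 < f <= 1.0) for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    if len(set(fr)) != len(fr):
        raise ValueError("fractions must be distinct")
    if not (v_max > 0):
        raise ValueError("v_max must be > 0")
    points = []
    for f in fr:
        try:
            sol = solve_steady_network(
                tree, outlets, f * v_max, fluid, inlet_area=inlet_area, kt=kt
            )
        except SolverError as exc:
            raise SolverError(f"constant-flow solve at fraction {f} failed: {exc}")
        dp = sol.inlet_pressure - sol.mean_outlet_pressure()
        points.append((f, float(dp)))
    return points


def fit_quadratic(
    points: Sequence[tuple[float, float]],
    v_max: float,
    constrain_origin: bool = True,
) -> ParametricFit:
    """Least-squares degree-2 fit in the (υₙ, Δp) parametric space.

    Needs ≥ 3 points with distinct υₙ (≥ 2 with the origin constraint,
    which fixes c₀ = 0). With exactly as many distinct points as free
    coefficients the fit interpolates exactly.
    """
    pts = [(float(v), float(p)) for v, p in points]
    distinct = len({v for v, _ in pts})
    needed = 2 if constrain_origin else 3
    if distinct < needed:
        raise ValueError(
            f"need at least {needed} distinct velocity values for the "
            f"{'origin-constrained ' if constrain_origin else ''}quadratic fit, "
            f"got {distinct}"
        )
    v = np.array([x for x, _ in pts])
    y = np.array([p for _, p in pts])
    if constrain_origin:
        design = np.column_stack([v, v * v])
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        c0, (c1, c2) = 0.0, sol
    else:
        design = np.column_stack([np.ones_like(v), v, v * v])
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        c0, c1, c2 = sol
    return ParametricFit(
        c0=float(c0), c1=float(c1), c2=float(c2), v_max=v_max,
        fit_points=tuple(pts), constrained_origin=constrain_origin,
    )


def predict_transient_gradient(
    fit: ParametricFit,
    waveform: InflowWaveform,
    times: np.ndarray | None = None,
) -> GradientSeries:
    """Predict Δp(t) by evaluating the fit at υ(t)/υ_max.

    Uses the waveform's own sample grid unless ``times`` is given. If
    the waveform exceeds the calibrated velocity range by more than a
    small slack, a warning is recorded and the series is flagged as
    extrapolated.
    """
    t = waveform.times if times is None else np.asarray(times, dtype=float)
    v_n = np.asarray(waveform.velocity(t), dtype=float) / fit.v_max
    extrapolated = bool(v_n.max() > 1.0 + EXTRAPOLATION_SLACK)
    if extrapolated:
        warnings.warn(
            f"waveform peak velocity exceeds the calibrated range "
            f"(max υₙ = {v_n.max():.3f}); prediction extrapolates",
            stacklevel=2,
        )
    return GradientSeries(times=t, dp=fit(v_n), extrapolated=extrapolated)


@dataclass(frozen=True)
class ErrorMetrics:
    """Discrepancy between a predicted and a reference Δp(t), in Pa.

    ``peak_relative_error`` is (max predicted − max reference)/max
    reference: positive when the parametric method overestimates the
    systolic peak.
    """

    max_abs_error: float
    mean_abs_error: float
    peak_relative_error: float

    @property
    def max_abs_error_mmhg(self) -> float:
        return float(pa_to_mmhg(self.max_abs_error))

    @property
    def mean_abs_error_mmhg(self) -> float:
        return float(pa_to_mmhg(self.mean_abs_error))


def parametric_error_metrics(
    predicted: GradientSeries,
    reference: GradientSeries,
    resample_tolerance: float = 1e-9,
) -> ErrorMetrics:
    """Elementwise error statistics between two Δp(t) curves over one cycle.

    If the grids differ, the reference is linearly interpolated onto the
    predicted grid (both must span the same interval to within
    ``resample_tolerance``).
    """
    tp, tr = predicted.times, reference.times
    if tp.shape == tr.shape and np.allclose(tp, tr, atol=resample_tolerance):
        ref = reference.dp
    else:
        if (
            abs(tp[0] - tr[0]) > resample_tolerance + 1e-6 * (tr[-1] - tr[0])
            or abs(tp[-1] - tr[-1]) > resample_tolerance + 1e-6 * (tr[-1] - tr[0])
        ):
            raise ValueError(
                "predicted and reference series span different intervals: "
                f"[{tp[0]}, {tp[-1]}] vs [{tr[0]}, {tr[-1]}]"
            )
        ref = np.interp(tp, tr, reference.dp)
    err = np.abs(predicted.dp - ref)
    t, e = tp, err
    mean_abs = float(np.trapezoid(e, t) / (t[-1] - t[0])) if t[-1] > t[0] else float(e.mean())
    ref_peak = float(np.max(ref))
    pred_peak = float(np.max(predicted.dp))
    peak_rel = (pred_peak - ref_peak) / ref_peak if ref_peak != 0 else np.nan
    return ErrorMetrics(
        max_abs_error=float(err.max()),
        mean_abs_error=mean_abs,
        peak_relative_error=float(peak_rel),
    )
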