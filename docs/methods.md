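# Methods

## Scope and model reduction

`pulmoflow` models the proximal pulmonary arterial tree as a 0D
(lumped-parameter) resistive network terminated by two-element
Windkessel outlets. This is a deliberate reduction of the full
image-based 3D finite-element approach to CTEPH assessment: the
clinical decision metrics — inlet-to-outlet pressure gradients, the
left/right flow split at peak systole, and summary wall shear — are
boundary-condition-level quantities, and the Windkessel coupling that
largely determines them is preserved exactly. What the reduction gives
up is the 3D flow field: vortices, helical flow, recirculation zones
and the full wall-shear-stress distribution are outside this package's
scope, as is any image segmentation or meshing. Wall shear is reported
only as the Poiseuille estimate `τ = 4μ|Q|/(πr³)` per segment.

## Network model

* **Segments.** Each vessel is a cylinder with a Poiseuille resistance
  `8μL/(πr⁴)` evaluated at the *effective* (stenotic where narrowed)
  radius. Walls are rigid; there is no inertance element, so the
  network has no state of its own and transmits flow instantaneously
  (one consequence: inlet flow equals the sum of outlet flows at every
  instant, which the solver reports as a per-step balance residual).
* **Stenosis.** A focal stenosis of severity `(D₀−Dₛ)/D₀` adds a
  turbulent-expansion loss `Kt·(ρ/2)·(1/Aₛ−1/A₀)²·Q|Q|` in series
  (Young–Tsai form). `Kt = 1.52` by default, configurable. The loss is
  quadratic in flow — the property the degree-2 parametric fit relies
  on — and odd in Q so reverse flow is handled.
* **Outlets.** Two-element Windkessel `Q = p/R + C·dp/dt` against zero
  distal pressure. Branch-level resistances (per-side totals of
  ~10⁸ Pa·s/m³, severe-pulmonary-hypertension magnitude) are converted
  to per-outlet values by parallel equivalence, `R_outlet = R_branch ×
  n_outlets`. Total compliance defaults to the stroke-volume over
  pulse-pressure estimate (8·10⁻⁵ m³ / 40 mmHg ≈ 1.5·10⁻⁸ m³/Pa) and is
  distributed **proportionally to outlet conductance** (`C_i ∝ 1/R_i`),
  giving every outlet the same RC time. This mirrors the near-constant
  resistance–compliance product of the pulmonary bed; an equal split
  would give physiologically implausible per-outlet time constants and
  make the systolic flow surge distribute by outlet count rather than
  by vascular impedance.
* **Fluid.** ρ = 1056 kg/m³, μ = 3.5 cP.

## Synthetic morphology

The generator builds deterministic idealized trees: MPA (generation 1)
→ LPA/RPA (generation 2) → symmetric bifurcations, with the last
generation fanning out to the requested per-side outlet counts (extra
leaves on the last internal branch, in id order). Diameters shrink by a
fixed taper per generation, and lengths follow `L = 3d` (a physiologic
length-to-diameter ratio; the tree's resistances then scale sensibly).

The default study morphology is a 5-generation, 31+29-outlet tree with
a 30.3 mm MPA (inlet area ≈ 723 mm²) and a taper of 0.44 per
generation, which ends in ~3 mm outlets and ≈ 420 mm² of total outlet
area — segmental-level calibers consistent with reported CT
segmentations of the pulmonary tree down to the third branching
generation. Caliber realism matters more than it may seem: with fat
(centimetre-scale) outlets the tree itself offers almost no resistance,
the flow split decouples from the vasculature, and neither the
resistance sweep nor paper-scale pressure gradients can be reproduced.
The builder's own `taper` argument defaults to a gentler 0.2 for
generic use; the pipeline configuration overrides it as above.

What the generator does **not** emulate: anatomical asymmetry between
left and right branch diameters, inter-patient variability in branch
lengths and angles, distributed (non-focal) disease, and real CT
segmentation noise. Passing tests on these trees demonstrate the
correctness and qualitative behavior of the methods, not patient-level
predictive accuracy.

## Inlet waveform

A half-sine systolic pulse on [0, 380 ms] riding on a constant
diastolic plateau over (380, 925] ms, scaled so the peak is exactly the
configured maximum velocity (default 0.5732 m/s). The plateau defaults
to 5% of peak — pulmonary inflow in diastole is nearly zero — and the
waveform is continuous and periodic by construction. The analytic form
is retained so the solver evaluates velocities exactly; file-loaded
waveforms are interpolated linearly.

## Numerics

* **Steady solves.** The linearized tree is reduced by an upward
  Thevenin sweep (leaf: `R_seg + b` against offset `a`; internal node:
  parallel combination) and flows/pressures recovered downward — O(n)
  per solve, conservation exact by construction. Stenosis elements are
  linearized as `R_eff = R_pois + K|Q|` and iterated: warm-started
  Picard (relative tolerance 10⁻¹⁰, cap 200), falling back for the
  single-stenosis case to a bracketed Brent root-find on the stenotic
  segment's flow, which is guaranteed because that flow is strictly
  decreasing in the branch resistance with fixed sign (Thevenin
  argument), so the root is unique and bracketed by [0, F(0)].
* **Transient solves.** Backward Euler on every Windkessel
  (unconditionally stable at the stiff RC outlets; default dt = 1 ms),
  with each step's nonlinear network solved with the outlet ODE folded
  in as a Thevenin termination — the discrete mass balance then holds
  to round-off. Three cycles are simulated and metrics use the final
  cycle only.
* **Periodic initialization.** With physiologic RC times (~seconds,
  longer than the 0.925 s cycle) a cold start cannot reach a periodic
  state in three cycles. The default initialization therefore warms
  each outlet at its steady operating point for the cycle-mean
  velocity, runs two unstored spin-up cycles, and extrapolates the
  per-outlet cycle-boundary pressures geometrically to the fixed point
  of the cycle map. Measured periodicity defects of the stored cycles
  are ~10⁻⁴ of pulse pressure (vs ~10⁻¹ from a cold start). "zero" and
  explicit-state starts remain selectable.

## Boundary-condition personalization

1. **Flow-size curve.** `f(s) = exp(β(s−1))`, fitted by log-linear
   least squares through the constrained point f(1)=1. The shipped
   default β = 0.9 is a stand-in of plausible magnitude, *not* a
   published fit — the underlying clinical calibration data are not
   distributed with this package; users supply their own points.
   Only this single-exponent constrained form is implemented.
2. **Size ratio.** Defaults to the effective proximal (LPA/RPA)
   cross-sectional area ratio; a total-outlet-area variant is exposed.
3. **Sweep.** A uniform multiplier on the stenosed side's outlet
   resistances, bisected on a log scale over [10⁻², 10²] until the
   peak-systolic flow ratio of a full transient solve is within 1%
   (relative) of target; compliances fixed. Monotonicity of ratio in
   the multiplier is checked on every run's evaluations. A cheaper
   steady-at-peak-velocity mode exists and is flagged as such.
   The achievable ratio band is physically limited — a severe stenosis
   caps the stenosed branch's peak flow share no matter how small its
   outlet resistance — and an out-of-band target raises an error
   naming the achievable bracket rather than returning a best effort.

## Metrics and conventions

* Δp(t) = inlet pressure − unweighted mean outlet pressure, final cycle
  only (a flow-weighted average is available behind a flag).
* Peak systolic PG = max over [0, systole end]; mean PG = trapezoidal
  cycle average; DPG = diastolic-interval time average. The clinical
  DPG involves the wedge pressure, which has no analog here; the
  diastolic gradient is its documented simulation counterpart, and the
  7 mmHg distal-remodeling flag is reported as an annotation only,
  never as decision logic.
* Flow ratio = stenosed-side over non-stenosed-side outlet flow at the
  instant of peak inlet flow in the final cycle.
* Percent change = 100·(post − pre)/pre at full precision; rounding
  (2 decimals for mmHg, 1 for percent, 2 for ratios) happens only at
  presentation.
* Internally everything is SI; mmHg enters only through the single
  constant 1 mmHg = 133.322 Pa.

## Parametric (constant-flow) estimator

Steady solves at 0.25/0.5/1.0 × peak velocity (independent — any
execution order gives bit-identical results), a degree-2 least-squares
fit in (υₙ, Δp), and evaluation along the waveform. The origin
constraint (c₀ = 0) is ON by default — zero flow gives zero gradient in
a rigid network — while the unconstrained 3-point interpolation is
selectable; on origin-passing data the two coincide. The steady
asymptote is computed by the direct steady solve rather than by
time-marching: same fixed point, a fraction of the cost.

In the quasi-steady (C → 0) limit the prediction matches the transient
gradient pointwise to well under 0.5% of the systolic peak (residual
error: the flow split drifts slightly with velocity, so Δp is not
perfectly quadratic). With physiologic compliance the estimator
*overestimates* the transient systolic peak in stenosed morphologies —
the compliant outlets buffer part of the systolic surge away from the
high-loss stenotic branch, which the constant-flow solves cannot see.
The magnitude of that overestimate is strongly model- and
severity-dependent (from a few percent to severalfold on the synthetic
cases) and is not asserted anywhere; in the non-stenosed arm the
estimator is nearly exact and its small bias can take either sign.

## Deliberately open design points, resolved as follows

* Tuning measures the flow ratio on a full transient solve (matching
  how the reported ratios are defined); the steady shortcut is opt-in.
* The virtual-surgery arm keeps the outlets tuned on the stenosed
  morphology, so pre/post differences isolate the geometric effect of
  stenosis removal.
* The severity-comparison study (37.1% vs 71.5%) uses published
  per-severity branch resistances directly as boundary conditions
  instead of re-sweeping: curve-derived targets fall outside the severe
  case's achievable peak-systole band.
* Near-balanced cases reproduce the known rounding quirk of flow-ratio
  percent changes: computing from rounded ratios (0.86 → 0.92) gives
  7.0% where unrounded splits (46/54 → 48/52) give 8.4%; the package
  always computes at full precision.

## Known limitations

* 0D reduction: no velocity fields, no 3D WSS, no flow topology.
* No inertance and rigid walls: systolic pressure wave shapes are
  simplified; the parametric-vs-transient discrepancy therefore comes
  entirely from compliance, not from unsteady inertia as it would in a
  3D model.
* Absolute pressure-gradient magnitudes depend on the synthetic
  morphology and are not patient-level predictions; directions and
  relative changes are the meaningful outputs.
* The flow-size curve exponent is a placeholder constant unless
  calibrated with user-supplied data.
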