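# Methods

## Tissue model and solver

The probe's fate in tissue is a linear three-pool chain — free probe C1,
covalent probe–enzyme complex C2, tissue CO₂ C3 — driven by a plasma
curve Cp(t) (see README for the equations). Assumptions: first-order
exchange throughout, irreversible covalent binding (no k_off), hydrolysis
as the complex's only exit, and CO₂ leaving tissue much faster than it is
produced (k5 ≫ K_H). The optional k4 pathway (CO₂ re-entering from a
plasma CO₂ pool) is off by default and requires an explicit second input
curve; whether the plasma pool is shared or separate is left to the user,
since either choice is defensible.

All rates are handled internally in 1/min; K_H is surfaced in 1/h, the
field's reporting convention (`RateConstants.kh` ↔ `kh_per_min`).

The forcing is biexponential, so the ODE system is solved **exactly**:
the plasma exponentials are appended to the state vector, making the
system autonomous, and the state is advanced by matrix exponentials
between breakpoints (output times, input delays, rate-switch times).
Rate constants may be piecewise-constant in time — `[(0, rc), (20,
rc_blocked)]` — which is how the blocking (k3 at 5 % from t=0) and chase
(k3→0 at 20 min) scenarios are built. Frame-averaged TACs
(`simulate_tac`) carry running integrals of C1..C3 in the augmented
state, so frame means are exact rather than quadrature approximations;
`frame_average` of an arbitrary callable uses adaptive quadrature at
1e-12 tolerance. This construction has no stiffness limit, which matters
because k5/K_H ≈ 150 in the brain regime.

Tests cross-check the solver against an independent stiff integrator
(Radau at rtol 1e-11) to ≤ 1e-6 relative error on randomized parameter
sets, and verify the analytic washout limit: with the input gone, total
activity tracks e^(−K_H·t) to within the quasi-steady CO₂ fraction
K_H/(k5−K_H).

## K_H estimation

`fit_monoexp` fits A·e^(−a·t) to frame midpoints (converted to hours)
inside a 15–90 min window by bounded non-linear least squares
(a ∈ [0, 20] h⁻¹). Initialization is a log-linear regression on the
positive in-window values; non-positive values (possible under noise)
stay in the least-squares objective but are excluded from the
initializer. Weights are uniform by default with optional
frame-duration weighting. The estimator reports the clearance rate as
K_H without subtracting k5 effects — in the k5 ≫ K_H regime the residual
bias is below 1 % (the noise-free round-trip tests see ≈ 0.2 %). Flat
data degenerates cleanly to a = 0.

Midpoint-in-window selection means the default window's first usable
frame is the 14–16 min frame (midpoint 15.0). Shifting the window start
from 15 to 20 min moves the estimate by < 3 % in the intended regime
(tested), so the exact window boundary is not critical.

## pH response

Hydrolysis activity vs pH is a four-parameter base-10 logistic with
half-max at pH 5.3, hill slope 1, floor 0, ceiling 1. Only the half-max
point is experimentally constrained; the slope default is a standard
dose–response choice and user-settable, and the in-vitro curve is not
claimed to calibrate the in-vivo pH→K_H relation — `modulated_kh` is a
configurable component. Severe-acid loss of binding affinity (below
pH 4.8) is modelled separately as a multiplier on the association rate
(k_on/k3), not on K_H, because it reflects the enzyme's binding, not the
hydrolysis chemistry; it is off by default.

## In-vitro CO₂-collection assay

A closed five-pool system in %ID: unbound probe, complex, dissolved CO₂,
bubbling trap, and a non-specific/pellet pool. The pellet partition is an
instantaneous fixed fraction at t=0 (default 25 %) — a fixture choice, as
the pellet kinetics are not characterized; it places the remaining pools
in the observed ranges (≈ 0.6 / 37 / 37 %ID unbound/complex/CO₂ at 60 min
with the defaults k_on = 0.08 min⁻¹, kh_max = 0.9 h⁻¹ at pH 7.4).
Bubbling is first-order removal of dissolved CO₂ (default 1 min⁻¹). The
linear mode is solved by matrix exponentials (conservation to machine
precision); the enzyme-capacity mode integrates with Radau at rtol 1e-11.
Capacity mode tracks *cumulative* occupancy — hydrolysis does not free
enzyme — so the complex pool saturates at B_max, matching the observed
~35 %ID plateau; it is off by default since the enzyme concentration is
unknown.

`ph_sweep` reports, besides the final pools, an estimated CO₂-production
rate: cumulative CO₂ divided by the integrated complex exposure ∫C2 dt
(carried exactly in the augmented state). `fit_ph50_from_sweep` fits the
logistic to this normalized rate rather than to final trapped %ID,
because the final amount is a saturating nonlinear transform of the rate
and would bias the recovered half-max; with the rate, a noise-free sweep
recovers ph50 to < 0.001.

## Parametric mapping

`relative_kh_map` is frame arithmetic only: plain (unweighted) means of
frame blocks 3–10 and 11–26 (1-based indices; the nominal "2–15 min" /
"15–90 min" labels are approximate — frame 10 ends at 16 min — and the
indices are taken as operational). Voxels with early mean ≤ 0.2 SUV are
masked (delivery too low for a reliable ratio), counted and set NaN.
Values are not clipped: negative values flag net late accumulation, the
signature of an irreversible but non-hydrolyzable tracer. Optional
Gaussian smoothing (FWHM in mm) before averaging is off by default. For
a mono-exponential voxel the map value 1 − mean_late/mean_early is
strictly increasing in K_H (verified over 0.1–2 h⁻¹) and invariant to
global intensity scaling.

## Synthetic data

The generator encodes the study conditions as named scenarios on the
26-frame/90-min schedule (1 min × 4, 2 min × 8, 5 min × 14):

- **Input function**: Cp(t) = 12·(e^(−0.4t) − e^(−4t)) SUV (minutes) — a
  bolus rise-and-fall peaking at ~0.64 min, with Cp(15 min) < 0.4 % of
  peak, satisfying the "negligible by 15 min" premise. No measured
  plasma parameters exist for this probe class; the shape is constrained
  only by that extinction property and a plausible peak.
- **healthy**: six regions with K_H 0.66 / 0.75 / 0.71 / 0.71 / 0.72 /
  0.69 h⁻¹ (cortex, striatum, hippocampus, thalamus, pons/medulla,
  cerebellum). K1 varies by region (0.096–0.114 ml·ml⁻¹·min⁻¹, frozen
  once from the solver) so noise-free peaks span the observed 1.6–1.9
  SUV while clearance stays region-invariant. k2 = 0.3, k3 = 0.6 min⁻¹
  are fixture values placing the model in the mono-exponential regime
  (free probe essentially trapped by 15 min); they are not measured.
- **mcao_1h / mcao_3_4h / mcao_6h**: contralateral K_H 0.62 / 0.62 /
  0.67, ipsilateral 0.47 / 0.41 / 0.56 h⁻¹; lesion K1 at 30 % of
  contralateral (the reported delivery deficit).
- **blocked** (k3 at 5 % from t=0), **chase** (k3→0 at 20 min),
  **hppc_like** (K_H = 0, the non-hydrolyzable comparator, delivery set
  for a ~1.2 SUV plateau).

The phantom is a schematic two-hemisphere ellipsoid (default 64×64×32 at
0.5 mm) with an ellipsoidal lesion in one hemisphere — not an anatomical
atlas. Noise is zero-mean Gaussian with SD = level·value/√(duration in
min), the standard frame-weighted TAC approximation; it is declared, not
derived from measurements. All stochastic output is a pure function of
(spec, seed).

What passing tests therefore show: the estimators and the map recover
the parameters of data generated by the same family of models under
PET-like frame binning and noise. They do not validate against
reconstruction noise correlations, partial-volume effects, motion,
anatomical geometry, or plasma-curve misspecification, none of which the
generator emulates.

## Problem sizes and numerical choices

Default test/bench sizes: 26-frame TACs, 100-replicate Monte-Carlo loops
for noise studies, 64×64×32 phantom for the zero-noise mapping check and
16×16×8 for replicated noisy phantoms — sizes chosen to exercise every
code path at full fidelity while keeping a complete run in minutes on one
core. Tolerances: solver vs oracle 1e-6 relative; assay conservation
1e-9; frame-average quadrature 1e-12; fit convergence tolerances 1e-14.
Ties/degenerate inputs: flat TAC → K_H = 0; empty ROI, zero reference
frame, non-contiguous schedules, negative rates → `ValidationError`.

## Known limitations

- K_H is identified with the late clearance rate; no k5 correction or
  full four-parameter compartmental fit from data is provided.
- The relative map is relative only — no conversion to absolute h⁻¹.
- The pH→K_H link is a modelling assumption configurable by the user,
  not a calibrated transfer function.
- No image-derived or sampled input functions, metabolite correction
  beyond the CO₂ pathway, or scanner-level effects.
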