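# Methods

## Physical model

A wetting liquid in a vertical microcapillary rises under the Laplace
pressure drop across the meniscus and is resisted by the hydrostatic head
of the raised column and by viscous wall friction. For the elliptical
bores of melt-extruded multi-bore strips (full major/minor axes *a*, *b*)
the driving pressure is

    ΔP_L = 2 σ_eff (1/a + 1/b),        σ_eff = cos(θ) · γ,

which reduces to 4 σ_eff / d for a circular bore. Friction is the
laminar Darcy–Weisbach drop with f_D = 64/Re evaluated over the total
wetted length *L* and the hydraulic diameter d_h = 4A/P (ellipse
perimeter by Ramanujan's first approximation, < 0.01 % error at the
aspect ratios of real strips, ≤ ~1.3); algebraically this collapses to
the Hagen–Poiseuille form 32 μ L u / d_h². The head is ΔP_H = ρ g H.

At the Reynolds numbers of microcapillary rise (Re < 10 throughout; a
warning flag trips at Re ≥ 2000) inertia is negligible, so the balance
ΔP_L = ΔP_F + ΔP_H is quasi-steady and linear in the superficial
velocity:

    u = max(0, (ΔP_L − ρ g H)) · d_h² / (32 μ L).

The clamp at zero encodes that the model does not describe meniscus
retreat. Setting u = 0 gives the equilibrium height H_eq = ΔP_L/(ρ g),
which contains no viscosity — endpoint measurements alone can never
identify μ, and `equilibrium_only_fit` reports that status explicitly.

Key identities used for validation:

- gravity-free limit (g = 0, L = H): H(t) = √(ΔP_L d_h² t / 16 μ), the
  classical √t law (`washburn_height`);
- L ≈ H regime: u = s·(1/H) + c with slope s = ΔP_L d_h²/(32 μ) and
  intercept c = −ρ g d_h²/(32 μ), so a straight line through (1/H, u)
  identifies both σ_eff and μ in closed form;
- wall shear rate γ_w = 8u/d_h (laminar tube flow), which at the
  observed 10–30 mm/s velocities and 156–261 µm bores stays within the
  physiological 100–800 s⁻¹ range.

## Units and parameters

Internal computation is strict SI. Interfaces accept/emit mm, cP
(1 cP = 1 mPa·s), mN/m and degrees. Defaults that matter:

| parameter | default | why |
|---|---|---|
| gravity g | 9.81 m/s² | standard |
| dip depth L_dip | 3 mm | submerged strip end; regularizes the L→0 singularity |
| RK4 step | 1 ms | converges to < 0.05 % on step halving |
| frame rate | 6 fps | imaging cadence of the emulated instrument |
| height noise σ | 1 % multiplicative | observed replicate scatter scale |
| frame-time jitter | ±20 ms uniform | capture-timing variability |
| strip layout | 12 strips × 10 bores | instrument capacity (120 capillaries) |
| bore profile | outer two bores × 0.96 | middle-eight-wider extrusion pattern |
| diameter CV | 9.4 % lognormal | printed scatter of the smallest bore (±14.63/156.3) |
| bore aspect ratio | 1.25 | representative ellipticity |
| fixed densities | 998 / 1005 / 1025 / 1055 kg/m³ | water / saline / plasma / whole blood; densities are fixed, never fitted |

Sample presets carry the combined σ_eff and viscosity used as generating
parameters (water 0.025 N/m, 1.04 cP; plasma 0.023–0.024 N/m, 1.70 cP;
red cells 0.034 N/m, 2.86 cP; whole blood 0.034 N/m, 4.58 cP). The RBC
suspension density (1045 kg/m³) is a config default for washed cells in
buffer. Glycerol–water mixtures (0/20/40/60 % w/w) use 20 °C handbook
values (ρ 998/1047/1099/1154 kg/m³, μ 1.005/1.76/3.72/10.8 cP, γ
72.8/71.7/70.6/69.0 mN/m) with a 61° contact angle on the hydrophilic
coating; these mixtures carry explicit γ and θ so the full equilibrium
inversion (`contact_angle_from_equilibrium`) is exercised on them.

## Synthetic-data generator

`flow_simulator` integrates dH/dt = u(H, t) with L = H + L_dip by a
fixed-step classical Runge–Kutta scheme, vectorized over arbitrary
batches of capillaries (a 12 × 10 array or a 2000-trajectory Monte-Carlo
sweep integrates in one pass). The ODE is singular at L = 0, so runs
start with the dipped portion already filled (H(0) = 0, L(0) = L_dip);
limit studies may instead start from a positive initial height. Frame
sampling interpolates linearly inside an integration step (O(dt²)), and
per-frame jittered sample times emulate capture-timing error while the
nominal stamps are reported. Measurement noise is multiplicative
Gaussian on the sampled heights. Identical (layout, config, seed)
reproduce bitwise-identical collections.

Thrombin-like stimulation is modelled as a single time-varying viscosity
multiplier μ(t) = μ₀ [1 + (k − 1)·logistic((t − t_on)/τ)]. The mapping
from loading dose to (k, t_on) is a **synthetic stand-in** — the
effective stimulus concentration in the rising column is not
experimentally accessible — chosen once as k = 1 + 5·dose/(dose + 30)
capped at 6 and t_on = 900/(30 + dose) s with τ = 1.5 s, so the highest
dose (150 U/mL) acts within 10 s and the lowest (5 U/mL) within 10–30 s.
When μ(t)/μ₀ reaches the blockage threshold (default 20×) the column is
frozen and the gelation time recorded. Spatial coagulation gradients
along the column and stimulation-induced surface-property changes are
deliberately not modelled.

What the generator does **not** emulate: shear-rate-dependent blood
rheology (including the Fåhræus–Lindqvist diameter effect reported to
matter at ~270 µm), inertial startup, dynamic contact angles, meniscus
curvature optics, lens distortion, or reagent dissolution kinetics.
Passing tests therefore demonstrate the internal consistency and
statistical behaviour of the analysis chain under the stated noise
model, not its accuracy on real blood.

## Imaging stage

The renderer draws each capillary as a fixed pixel-column range, liquid
dark (level 60) on light background (230), rows filled from the
reservoir baseline up to H/scale with the top partial pixel linearly
blended — the sub-pixel meniscus position is therefore encoded in one
pixel's intensity. Pixel scale defaults to 0.1 mm/px and is fully
configurable (the emulated camera's true scale is not pinned down).
Frames are written as multi-page grayscale TIFF with a JSON sidecar
(timestamps, scale, column registration, baseline row).

Tracking scans each registered column's mean-intensity profile upward
from the baseline. Wet and dry levels are calibrated per profile (wet:
median of the 3 rows above the baseline; dry: median of the top 5 rows,
which the renderer's headroom keeps dry), making detection invariant to
global intensity offsets. The meniscus is localized at the first
crossing of the wet/dry midpoint and its sub-pixel position is then read
from the summed coverage of the two bracketing pixels, which is exact
for a linear partial-pixel edge; plain linear interpolation between
pixel centres was measured to carry a ~0.09 px systematic bias — small
for heights, but large enough to break percent-level velocity estimates
after finite differencing. Accuracy: ≤ 0.01 px noiseless, ≤ 0.05 px at
pixel-noise σ = 2. A column with no wet/dry transition reports height 0
(not wetted); once wetted, a detection failure carries the previous
height forward with a quality flag.

Velocity estimation differences pairs of height samples, assigning the
value to the pair's time midpoint and pairing it with 1/H at the
midpoint height. Pair spacing is adaptive: consecutive frames (1/6 s)
while t < 3 s, then growing as a power of t to ~2 s by t = 30 s —
early the meniscus is fast and short baselines resolve it; late the
meniscus creeps and longer baselines suppress timing noise. Trailing
pairs that cannot achieve their full spacing are dropped rather than
shortened. Negative differences are clamped to zero and flagged in
`velocities`; the raw signed values are kept in `signed_velocities`.

## Parameter fitting

`linear_transient_fit` is the closed-form route: weighted OLS of u on
1/H, viscosity from the (negative) intercept, σ_eff from the slope. A
non-negative intercept means the data never resolved the gravity term;
the fit is flagged and μ left undetermined rather than reported.

`constrained_fit` is the production route: box-constrained least squares
(scipy trust-region reflective) on the full model (L = H + L_dip, u
clamped at equilibrium) over pooled capillaries with their individual
geometries, seeded from the linear fit. Two estimator choices matter and
were made on statistical grounds:

- residuals are computed against the **signed** finite differences;
  fitting the rectified (≥ 0) velocities would bias both parameters
  upward wherever the true velocity is comparable to the noise (late
  times), since rectified noise has positive mean;
- observations faster than 20 mm/s are down-weighted by 1/u (they come
  from very short inter-frame baselines where timing error dominates),
  and the weights are refreshed once from the model prediction (a single
  IRLS step) so that they do not correlate with the noise realization.

Viscosity bounds per sample class mirror the expected physiological
ranges (water/saline fixed at 1.04 cP; plasma < 1.7 cP; cellular samples
2–6 cP); the report records each bound and whether it is active.
Density is always fixed. For blood-like samples only σ_eff is reported —
γ and θ are not separately identifiable without an independent surface
tension, which only the glycerol workflow supplies.

Stimulation read-out overlays fixed-multiplier model curves (default 2×,
3×, 4×, 6× the baseline viscosity, σ_eff held fixed) on the u-vs-1/H
data. Each observation is assigned to its nearest curve by absolute
velocity residual (ties to the smaller multiplier); the onset estimate
is the first time the best match exceeds baseline, and the terminal
multiplier is the last point's match. With the default ramp this
detector recovers scheduled onsets to within ~4 s and preserves dose
ordering.

## Numerical choices and degenerate inputs

- RK4 step 1 ms (10 ms for the long equilibrium runs); step halving
  changes final heights by < 0.05 %. The integrator raises if a step
  ever produces a decreasing height.
- Equilibrium studies integrate 600 s, enough for the slowest case (60 %
  glycerol, largest bore) to close within 0.1 % of H_eq.
- The Monte-Carlo recovery study simulates all replicates in one batch:
  200 replicates × 10 capillaries × 30 s in ≈ 4 s.
- Zero wetted length raises a singular-state error; zero dip depth
  requires a positive initial height. H > H_eq clamps u to 0. Implied
  cos θ outside (0, 1] raises an infeasible-observation error.
- Tie-breaks: equal classification residuals resolve to the smaller
  multiplier; axes must be passed ordered (a ≥ b), never swapped
  silently.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own validation scale: 1000-draw closure sweep;
full glycerol suite (4 mixtures × 3 diameters, 600 s); 200-replicate
recovery study per diameter (100 in the acceptance script); one-strip
(10 capillary) imaging round trip over 30 s at 6 fps; the full
five-dose stimulation panel. The complete test suite runs in well under
a minute on one CPU.

## Known limitations

- The velocity-accuracy statement for tracked data holds in the
  resolvable band (analytic u between 1 and 20 mm/s, t > 3 s): below
  1 mm/s the meniscus moves less than the 0.1 mm/px resolution over a
  2 s baseline, so percent-level relative accuracy is not measurable at
  the default optics.
- The dose → ramp mapping is calibrated to qualitative timing statements
  only; absolute dose–response numbers produced with it characterize the
  synthetic model, not an assay.
- A single time-varying μ(t) cannot distinguish viscosity increase from
  surface-drive loss; the classification read-out inherits that
  ambiguity from the model.
- Equilibrium-derived contact angles (θ ≈ 61° for water) and
  transient-fit surface drives (σ_eff = 0.025 N/m, implying a larger
  dynamic angle) are deliberately kept as separate outputs; the model
  does not reconcile static and dynamic wetting.
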