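# Methods

This note documents the models, parameters and numerical choices behind
`oftflow`: what the synthetic outflow tract (OFT) generator emulates, how the
wall-motion metrics are defined, how the quasi-steady flow problem is
discretized and inverted, and what the validation suite does and does not
establish about real optical-coherence-tomography (OCT) data.

## 1. Synthetic 4D outflow tract

The generator is a fully analytic kinematic model; every emitted mesh is a
sample of closed-form contour functions, so areas, perimeters, cushion gaps,
closure windows and the pressure-drop schedule are known exactly and are
carried alongside the meshes as ground truth.

**Geometry.** The centerline is a planar circular arc in the x–z plane
(curvature 900 m⁻¹ by default, i.e. ≈ 0.72 rad of turn over the tube) whose
inlet tangent is tilted 0.35 rad toward the scene vertical. The vertical
(z) axis is the OCT beam direction, so axial flow always has a measurable
beam component at the probe. The lumen radius tapers linearly from 150 µm at
the inlet (ventricle end) to 100 µm at the outlet (aortic-sac end) over an
800 µm tube — stage-HH18 scale. The inner myocardium contour sits
30 µm outside the fully expanded lumen (the cardiac-jelly layer, which the
cushions locally thicken).

**Cross-section shape.** Each lumen cross-section is an ellipse whose
semi-axis `a` lies along the cushion-apposition axis (θ = 0 points to the
inner curvature, where one cushion sits; the other is opposed at θ = π) and
`b` along the slit axis, multiplied by a raised-cosine cushion indentation
(amplitude 0.25 of local radius, angular half-width 0.9 rad) that deepens as
the wall contracts. During contraction `a` shrinks to zero while `b` only
shrinks by `slit_axis_ratio` (0.35), so the lumen passes circular →
elliptical → slit and closes completely; the myocardium contour stays
near-circular and contracts with amplitude 0.2 of the lumen's. This makes
lumen ASF and strain larger than their myocardial counterparts, the
amplification produced by cushions acting on a modestly contracting wall.

**Cycle kinematics.** With local cycle phase
`u = t/T − lag·(s/L) (mod 1)`, each section is closed (slit) for
`closure_fraction` = 0.4 of its local cycle and opens following
`h(x) = sin(πx)` on the cushion axis and `sin²(πx)` elsewhere
(`x` the normalized open-window coordinate). The |sin| profile gives a
linear approach to cushion contact — a kinematic contact event — so the time
the gap dwells below instrument resolution is under one frame; the smooth
sin² drives every other quantity. The phase lag (0.15 cycles over the tube)
produces the traveling peristaltic wave: per-ring area maxima drift linearly
across the 2D area plot. With five analysis sections at normalized stations
1/6 … 5/6, the union of closure windows spans
`0.4 + 0.15·(5/6 − 1/6) = 0.5` of the cycle — the calibrated total-closure
fraction — and the whole tube is open for the remaining 0.45 of the cycle,
matching the ≈ half-cycle forward-flow window of the real OFT.

Defaults: period `T` = 0.4 s (2.5 Hz) sampled at 56 frames (7.14 ms spacing,
the 140 frames/s acquisition cadence). A closed slit carries a numerical
half-gap floor of 1 nm (area ≈ 3·10⁻¹³ m², four orders below the closure
threshold) so that plane sections of closed frames remain well-posed; a
`residual_gap` option raises this floor to emulate the 10 µm axial
resolution limit of the instrument.

**Band.** The banding intervention multiplies the local base radius by
`1 − (1 − tightness)·e(s)` and the local motion amplitude by
`1 − suppression·e(s)`, with `e` a raised-cosine envelope (half-width
100 µm) centered at normalized position 0.2 — between analysis sections 1
and 3, as placed surgically. Defaults `tightness` = 0.6,
`suppression` = 0.8 are assumptions (no tightness was reported for the
experimental sutures); with full suppression the band station's maximum
radius is exactly `tightness` × the unbanded radius, which the tests verify
by paired regeneration. Cushion indentation scales with the local amplitude,
so a fully suppressed band is motionless. The pressure-drop schedule
`Δp(t) = 20 Pa · sin²` over the all-open window drives peak velocities of
≈ 45 mm/s — chosen so the regime diagnostics land at Re ≈ 4 and Wo ≈ 0.3,
inside the viscous-dominated envelope reported for this stage.

**Inter-embryo variation.** Cohorts jitter radii, length, curvature and
`dp_peak` by a seeded uniform ±5%; the closure timing parameters are fixed,
so cohort-mean closure quantities are unbiased. All defaults are
deterministic; the seed only drives this optional jitter.

## 2. Wall-motion metrics

Per cross-section and layer (lumen; area enclosed by the *inner* myocardium
contour):

- `ASF = (A_max − A_min)/A_max`, with extrema over one cycle.
- `εθ(t) = |C(t) − C_max| / C_max` — compressive by construction, with the
  maximal perimeter over the cycle as the zero-strain reference; the
  reported value is the maximum (at maximal contraction).
- M-mode phase fractions along a line through the cushions, perpendicular to
  the closed slit: a frame is **closed** when the gap ≤ 10 µm (one axial
  resolution unit; the instrument cannot distinguish smaller gaps from
  contact). Open frames split into **expanding**/**contracting** by the sign
  of the cyclically smoothed gap derivative (3-frame moving average;
  zero-derivative frames split evenly), so the three fractions partition the
  cycle exactly.
- **Total closure fraction**: the fraction of the cycle during which at
  least one section is closed (logical OR over sections). The per-section
  indicator used here is area-based (lumen area below that of a circle with
  the 10 µm threshold as diameter), for which the sub-threshold dwell is
  negligible.

A resolution-limited instrument necessarily reads slightly more closed time
than the geometric closure window (the gap spends time nonzero but below
threshold). The generator therefore also exposes the *thresholded* closed
fraction (`GroundTruth.closed_fraction_at_threshold`), which is what the
M-mode analysis is validated against; at defaults it exceeds the geometric
window by about one frame.

Cross-sections are taken at five evenly spaced interior centerline stations
((i+1)/6, i = 0…4), with planes perpendicular to the centerline of the
most contracted frame (tie-break: minimum total lumen ring area). Sections
of structured surfaces are computed per angular index (one plane crossing
per axial polyline), which stays exact-ordered and robust for slit-collapsed
contours where generic mesh sectioning fails.

## 3. Consistent ring parameterization

Raw tube meshes are re-parameterized by: (i) centerline estimation (ring
centroids when structured; PCA-slab centroids otherwise, smoothed), (ii)
`n_rings` planes at uniform arclength with tilt-rate-clamped normals
(≤ 0.2 rad between neighbors, preventing plane crossings at high curvature;
end planes are nudged inward if they exit an open rim), and (iii) uniform
angular resampling of each contour about its centroid, anchored at the
projection of the inner-curvature direction of the first frame — a fixed
material landmark, so vertex trajectories are comparable across frames.
Angular resampling assumes contours star-shaped about their centroid, which
holds for ellipse-like sections with cushion indentation amplitude < 1. Area
and perimeter quantities are chart-independent, and the tests verify they
survive re-parameterization to < 1–2%; more elaborate strain-minimizing
correspondence is intentionally out of scope since only area-level
quantities feed the downstream analyses.

## 4. Quasi-steady Stokes flow

**Model.** At this scale (Re < 7, Wo < 0.5) inertia is negligible, so each
simulated frame solves steady Stokes flow on that frame's lumen:
`−μ∇²u + ∇p = 0`, `∇·u = 0`, with blood density ρ = 1060 kg/m³ and
viscosity μ = 0.003 kg/(m·s). Walls are no-slip with zero wall velocity —
wall motion enters only through the changing mesh — which is unreliable
exactly when flow velocities are comparable to wall velocities, i.e. near
lumen opening/closure; those frames are excluded (probe speeds below 2% of
the cycle maximum, plus any frame whose minimum ring area is below that of a
10 µm-radius circle). An `open_fraction` option further restricts the
simulated window to a contiguous span (the pipeline uses 0.51 for normal and
0.40 for banded scenarios).

**Boundary conditions.** The flow is driven by a single scalar, the
pressure drop Δp: pseudo-traction `−Δp·n` on the inlet face, `0` on the
outlet (the do-nothing form of the full-gradient weak formulation, for which
Poiseuille flow is an exact solution with uniform end pressures).

**Discretization.** Structured tetrahedral meshes fill each ring
cross-section with a centroid node plus `n_radial` linear radial layers;
prisms between rings are split 3-tets-per-prism with the minimum-global-index
diagonal rule, guaranteeing conforming faces (verified by face-count and
positivity tests). Elements are equal-order P1–P1 with Brezzi–Pitkäranta
pressure stabilization `−(α h²/μ)(∇p, ∇q)`, `h²` the mean squared element
edge. α = 0.01 was calibrated on the Poiseuille benchmark: it keeps the
pressure field oscillation-free while limiting the stabilization's
compressibility leak (per-section flow-rate spread 0.6% at validation
resolution, vs ≈ 4% at α = 0.1). The saddle system is solved by sparse LU;
velocity converges at second order in the L2 norm under refinement.

**Resolutions.** Surface default 40 rings × 32 angles, volume default 6
radial layers (≈ 41k tets, ≈ 31k dofs, a few seconds per solve). Flow-rate
and WSS accuracy are controlled by the *cross-sectional* resolution: the
solver validation gates (flow rate within 2% and WSS within 5% of the
Poiseuille closed forms) are run at 48 angles × 8 radial layers × 21 rings,
which delivers −1.0% on Q and ≤ 1.3% on WSS; at 32 × 6 the polygonal
boundary deficit alone costs ≈ 1.3% of Q (inscribed 32-gon) and the total is
≈ −2%. Band-station wall metrics need ring spacing ≲ 10 µm (second-order
convergence of the sampled band envelope; < 0.4% error at 80 rings vs ≈ 2%
at 40).

**Inverse Δp.** Stokes linearity makes the probe velocity exactly
proportional to Δp, so the fit against a Doppler measurement is one trial
solve plus scaling; the recovery is exact to solver precision (< 10⁻⁶
relative, in practice ≈ 10⁻¹⁵). A secant iteration is retained for
nonlinear extensions (e.g. reinstating convection). The fit is declared
unidentifiable when the beam-projected trial velocity is below 10⁻⁴ of the
trial's peak speed (beam ⊥ flow).

**WSS.** Wall traction is recovered by the variationally consistent
boundary-flux (residual) method — the discrete reaction at wall nodes
divided by the lumped wall mass — and WSS is the magnitude of its
tangential part; `WSR = WSS/μ` identically. This is one order more accurate
at the wall than differentiating the P1 field. Maps are reported on the
(normalized length × θ) grid with 50 µm margins at inlet and outlet excluded
(boundary-condition artifacts live there). On the curved tube the
inner-curvature side carries the larger WSS, and ring-averaged WSS grows
toward the outlet as the taper narrows (lubrication scaling WSS ∝ R⁻³ at
fixed flow rate); both are asserted as invariants.

**Diagnostics.** `Re = ρ·V_peak·D/μ` and `Wo = (D/2)·√(2πf·ρ/μ)`, with
`V_peak` the peak CFD speed over the simulated window and `D` the
area-equivalent diameter of the maximally expanded lumen at the mid-tube
station (station configurable). Defaults give Re ≈ 3.9 and Wo ≈ 0.29.

## 5. Doppler model

`Vz = λ·Δϕ/(4π·n·τ)` with defaults λ = 1310 nm, n = 1.35, τ = 21 µs; the
aliasing velocity is λ/(4nτ) ≈ 11.55 mm/s, and synthetic probe velocities
(up to ≈ 20 mm/s at the mid-OFT probe) deliberately exceed it so traces
emerge wrapped. Temporal unwrapping corrects inter-frame jumps > π by the
nearest multiple of 2π, processing each contiguous open-flow run
independently (closed gaps reset the phase), and warns when a corrected jump
exceeds 0.75π — the regime where sparse sampling makes the correction
ambiguous. Only the beam-direction component is ever compared to Doppler
data; no angle correction is attempted. Optional Gaussian phase noise is
available but off by default.

## 6. What the synthetic validation does and does not show

The generator provides exact ground truth, periodic noise-free geometry,
symmetric cushions, a static centerline (purely radial wall motion) and
ellipse-based contours. Passing tests therefore demonstrate the
*correctness of the implementations* — metric formulas, parameterization,
meshing, solver, inverse method, wrap handling — under realistic scales and
kinematics. They do not exercise: segmentation error or frame-to-frame
jitter of real OCT surfaces, asymmetric or irregular cushion anatomy,
centerline motion, non-periodic beats, Doppler noise (available but not part
of the gates), fluid–structure interaction, or wall-velocity effects near
closure (explicitly excluded frames). Group comparisons on synthetic cohorts
reproduce the banding pattern (contractility suppressed only at the band
station; elevated band-site velocity and WSS) by construction of the band
model, so they validate the *analysis chain*, not the biology.

## 7. Default problem sizes

Wall-motion analyses: 56 frames × (40 × 32) surfaces per embryo, cohorts of
7 control / 6 banded. CFD: ≈ 25 open-window frames at 41k tets each for a
full default cycle; the bundled reproduction script simulates every second
open frame (13 solves plus 13 synthesis solves, ≈ 4 min single-core) and a
7-embryo closure cohort (≈ 20 s). The test suite uses coarsened grids
(20–40 rings, 16–24 angles, 3–5 radial layers) chosen so each gate's
discretization error is several times smaller than its tolerance.
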