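# oftflow

Wall-motion quantification and embryo-specific quasi-steady CFD for the
embryonic heart **outflow tract (OFT)** — the curved, tapered, beating tube
that connects the early ventricle to the aortic sac and later forms the
semilunar valves and great-artery trunks.

At Hamburger–Hamilton stage 18 (day 3 of chick incubation, heart rate
≈ 2.5 Hz) the OFT acts as a primitive valve: two opposed endocardial cushions
press together once per cycle until each lumen cross-section closes into a
slit. Experimental interventions such as **outflow-tract banding** (a suture
partially constricting the OFT inlet) alter both the wall motion and the
hemodynamic load — notably the wall shear stress (WSS) sensed by endocardial
cells — and are widely used to study how disturbed flow drives congenital
heart defects.

`oftflow` implements the full analysis chain for 4D (3D + time) segmented OFT
surfaces, together with a synthetic 4D generator that emulates normal and
banded embryos with exact ground truth:

- **synth** — analytic generator of lumen/myocardium surface sequences:
  tapered arc tube, opposed cushions (circular → elliptical → slit closure),
  a peristaltic contraction wave traveling proximal→distal, optional band
  with locally suppressed motion, plus wrapped Doppler probe traces.
- **doppler** — Doppler OCT phase↔velocity conversion,
  `Vz = λ·Δϕ / (4π·n·τ)` (λ = 1310 nm, n = 1.35, τ = 21 µs by default),
  with ±π phase wrapping and temporal unwrapping.
- **geometry** — centerlines, cross-section extraction at 5 evenly spaced
  stations, consistent `n_rings × n_theta` ring parameterization over time,
  and structured tetrahedral volume meshing of the lumen.
- **wallmotion** — area shortening fraction
  `ASF = (A_max − A_min)/A_max`, compressive circumferential strain
  `εθ = |C − C_max|/C_max`, M-mode expanding/contracting/closed phase
  fractions, the union ("total") closure fraction, and 2D area plots
  (normalized time × normalized length).
- **hemo** — quasi-steady **steady-Stokes** finite-element solver
  (P1–P1 stabilized tetrahedra) on the moving lumen with a pressure-drop
  boundary condition Δp, inverse Δp estimation against a single Doppler
  probe velocity (one trial solve + linear scaling), WSS maps recovered by
  the consistent boundary-flux method, and Re/Wo diagnostics.
- **pipeline / CLI** — cohort runs (7 control / 6 banded by default), group
  mean ± SD summaries, and a thin `oftflow` command-line interface
  (`synth`, `metrics`, `cfd`, `run`, `compare`).

## Worked example

```python
import numpy as np
import oftflow as of

# 1. synthesize one normal embryo (HH18 defaults, 2.5 Hz)
lumen, myo, gt = of.generate_motion(seed=0)

# 2. wall-motion metrics at the five analysis cross-sections
most_contracted = int(np.argmin([f.ring_areas().sum() for f in lumen]))
centerline = of.compute_centerline(myo[most_contracted])
traces = of.extract_cross_sections(lumen, myo, centerline,
                                   times=gt.times, period=gt.period)
for tr in traces[:2]:
    strain = of.circumferential_strain(tr, "lumen")[1]
    print(f"section {tr.section_id}: lumen ASF = {of.asf(tr):.3f}, "
          f"max eps_theta = {strain:.3f}")
closure = of.total_closure_fraction([tr.closed() for tr in traces])
print(f"total closure fraction = {closure:.3f} of the cardiac cycle")

# 3. quasi-steady CFD over the open window (coarsened for the example)
lumen_c, _, gt_c = of.generate_motion(seed=0, n_rings=20, n_theta=24,
                                      motion=of.MotionParams(n_frames=32))
trace = of.synthesize_doppler(lumen_c, gt_c.dp, gt_c.probe_point,
                              gt_c.times, n_radial=4)
sim = of.simulate_cycle(lumen_c, trace, gt_c.probe_point, n_radial=4)
diag = of.hemo.diagnostics(sim.solutions, lumen_c, heart_rate=2.5)
idx = np.asarray(sim.frame_indices)
print(f"solved {len(sim.solutions)} open-lumen frames; "
      f"max |dp_fit - dp_true| = {np.abs(sim.dp[idx] - gt_c.dp[idx]).max():.2e} Pa")
print(f"Re = {diag.reynolds:.2f} (< 7), Wo = {diag.womersley:.2f} (< 0.5), "
      f"peak velocity = {diag.peak_velocity*1e3:.1f} mm/s")
```

Output:

```
section 1: lumen ASF = 1.000, max eps_theta = 0.585
section 2: lumen ASF = 1.000, max eps_theta = 0.586
total closure fraction = 0.500 of the cardiac cycle
solved 11 open-lumen frames; max |dp_fit - dp_true| = 8.88e-15 Pa
Re = 3.83 (< 7), Wo = 0.29 (< 0.5), peak velocity = 44.0 mm/s
```

Reading this: every lumen section closes fully once per cycle (ASF = 1, the
cushions meet), the maximal compressive endocardial strain is ≈ 0.59 against
the fully expanded reference, and at least one of the five sections is closed
for half the cycle — the OFT's valve-like behavior. The inverse method
recovers the driving pressure drop of every simulated frame to machine
precision (Stokes flow is linear in Δp), and the flow stays firmly in the
viscous regime (Re < 7, Wo < 0.5) that justifies the quasi-steady model.

The same run from a shell:

```sh
oftflow run --scenario paired --seed 1 --outdir out/   # cohorts + comparison
oftflow cfd --scenario normal --seed 1 --outdir out/   # adds the CFD stage
```

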