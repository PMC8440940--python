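# vortexlav

Lagrangian vortex-ring detection in 2D cine phase-contrast MRI velocity
fields, for researchers studying intracardiac blood-flow organisation
(e.g. the swirling filling pattern of the right atrium).

Cine phase-contrast MRI measures the in-plane blood velocity **v**(x, t)
on ~25 cardiac phases. That temporal resolution is too coarse to integrate
particle trajectories reliably, and instantaneous (Eulerian) vortex
criteria cannot follow a vortex ring as material object through the cycle.
`vortexlav` addresses both problems:

1. **Temporal densification.** Horn–Schunck optical flow is estimated
   between consecutive frames by minimising the classical energy

   E(u, v) = ∫ (I_t + I_x u + I_y v)² dx dy + α ∫ (|∇u|² + |∇v|²) dx dy,

   and intermediate frames at fraction t ∈ (0, 1) are fused by bilinear
   backward warping g along linearly scaled flows,

   Î_t = (1 − t) · g(I₀, −t F₀₁) + t · g(I₁, (1 − t) F₀₁),

   applied per velocity component. A linear-blend baseline is included.

2. **LAVD.** Particles seeded at every chamber pixel x₀ are advected with
   RK4 through the densified field, and the Lagrangian Averaged Vorticity
   Deviation

   LAVD(x₀) = ∫_{t₀}^{t₁} | ω(x(x₀, s), s) − ϖ(s) | ds

   is accumulated along each trajectory, where ω = ∂v/∂x − ∂u/∂y is the
   scalar vorticity and ϖ its instantaneous mean over the segmented
   chamber. LAVD is objective (invariant to superposed rigid rotations of
   the observer) and measures the net material rotation a particle
   experiences; half of it is the intrinsic rotation angle ψ.

3. **Ring extraction.** A vortex core is a strict local maximum of LAVD;
   its ring boundary is the outermost closed LAVD level curve around the
   core whose convexity deficiency (hull area − area)/area stays below
   d_max (default 1). Each ring reports a rotation sense (CW/CCW, from the
   mean vorticity over the enclosed pixels) and a volume
   = enclosed area × slice thickness.

Because no scan data could be redistributed, the package ships an analytic
scene generator (Rankine and Lamb–Oseen vortices, translating image
patterns) with closed-form LAVD and ring ground truth, and every stage is
validated against it.

## Worked example

A Rankine vortex (core radius a = 1, circulation Γ = π) centred in a disk
mask of radius 2 has vorticity 1 s⁻¹ in the core and 0 outside, so
ϖ = 0.25 s⁻¹ and the exact LAVD over T = 1 s is 0.75 rad inside the core
and 0.25 rad outside. `python examples/03_lavd_rankine.py` prints:

```
interior LAVD: 0.7494 rad   (closed form 0.75)
exterior LAVD: 0.2506 rad   (closed form 0.25)
intrinsic rotation angle at the core: 0.3747 rad
```

The measured plateaus match the analytic trajectory integral to better
than 1%. `python examples/04_vortex_ring_pipeline.py` runs the full
pipeline on a counter-rotating vortex pair:

```
detected 2 ring(s):
  sense CCW  core (42.0, 48.0) mm  area  1194.0 mm^2  volume 7.164 ml
  sense CW  core (54.0, 48.0) mm  area  1194.0 mm^2  volume 7.164 ml
```

Both imposed senses are recovered and each volume is the enclosed area
extruded through the 6 mm slice. The other examples demonstrate VENC
phase-to-velocity conversion and flow-warped frame synthesis (which
reconstructs a translating pattern with IE 0.09 vs 1.99 for the linear
blend).

A thin CLI mirrors the library stages
(`vortexlav synth|flow|upsample|lavd|rings|evaluate|run`); see
`vortexlav --help`.

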