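# Methods

## Problem and model

Cine phase-contrast MRI yields the in-plane blood velocity v(x, t) on a
single slice at ~25 cardiac phases, with velocity encoded in the signal
phase (±π ↔ ±VENC; conversion is linear, sign-preserving, and values
outside ±π are treated as aliasing errors — unwrapping is out of scope).
The package identifies rotationally coherent Lagrangian vortices in such
data in three steps: temporal densification of the velocity series,
trajectory integration of the vorticity deviation (LAVD), and extraction
of ring cores/boundaries from the LAVD map.

LAVD(x₀; t₀, t₁) = ∫ |ω(x(x₀, s), s) − ϖ(s)| ds along the trajectory
started at x₀, where ω = ∂v/∂x − ∂u/∂y is the scalar 2D vorticity and
ϖ(s) its instantaneous spatial mean over the analysis domain. The measure
is objective: superposing a rigid rotation shifts ω and ϖ by the same
constant, leaving the integrand unchanged. Half the LAVD is the intrinsic
material rotation angle ψ, which is additive over adjacent time windows
along the same trajectory.

## Coordinates and units

Grids are (row, col), 0-based; physical x = col·spacing, y = row·spacing
with y increasing downward. All internal math (advection, vorticity) is
done consistently in this left-handed frame, where the computed ω is the
negative of the conventional y-up vorticity. Sign conventions surface in
exactly one place: a ring's rotation sense is reported as CCW iff the
conventional vorticity over the enclosed pixels is positive (i.e. the
array-frame mean ω is negative). Canonical internal units are mm, s, mm/s
and rad; conversions (cm/s for VENC, ml for volumes) happen only at I/O
boundaries.

## Optical flow

Horn–Schunck flow minimizes the brightness-constancy + smoothness energy
with weight α, solved by the classical Jacobi fixed-point iteration
(4-neighbour averages, replicate boundaries, zero initialization —
deterministic and order-independent). Derivatives: central differences of
the two-frame average for I_x, I_y; I_t = I₁ − I₀. The denominator uses
α² + I_x² + I_y², the standard normal-equation form.

Defaults: α = 15 on a 0–255 intensity scale, max_iter = 2000,
tol = 1e-5 px mean absolute update. The tolerance is deliberately strict:
the Jacobi scheme propagates flow by diffusion, so per-iteration updates
fall to ~1e-3 px after a few dozen iterations while the recovered
displacement is still tens of percent short of its fixed point; a loose
tolerance silently truncates convergence. With these defaults a 1-px blob
translation is recovered to ~0.03 px. Velocity frames are normalized to
0–255 for flow estimation only (α is calibrated to that scale) and warped
on their native mm/s values.

## Frame synthesis

Intermediate flows use the constant-velocity approximation
F_{t→0} = −t·F₀₁ and F_{t→1} = (1−t)·F₀₁, and the intermediate frame is
the weighted sum Î_t = (1−t)·g(I₀, F_{t→0}) + t·g(I₁, F_{t→1}) with
bilinear backward warping g (out-of-domain samples clamp to the edge).
The temporal weight is a scalar; no per-pixel occlusion map is used, since
a single-slice velocity-encoded acquisition has no occluding objects. This
form is endpoint-consistent (Î₀ = I₀, Î₁ = I₁ bit-exactly). Velocity
series are upsampled per component as intensity images on the mm/s scale,
preserving original frames bit-exactly. The linear baseline is
(1−t)I₀ + tI₁.

## LAVD numerics

- Vorticity per stored frame by central differences (one-sided at edges);
  since velocity between frames is linear in time, the in-between
  vorticity and its mask mean are too, so both interpolate linearly.
- Spatial sampling of ω at particle positions is bilinear.
- Trajectories: classical fixed-step RK4; default dt = frame_interval /
  upsampling factor so steps land on synthesized frames; the last step is
  shortened to land on t₁. Seeds leaving the image domain freeze at exit
  and stop accumulating; seeds leaving the chamber mask but staying
  in-image continue (blood crosses chamber boundaries physically).
- Quadrature: trapezoidal rule on |ω − ϖ| (2nd order; trajectory error is
  4th order).
- ϖ(t) is averaged over the fixed analysis mask supplied at t₀; a
  different (e.g. per-frame) domain mask can be passed explicitly.
- Default analysis window: 2 original frame intervals, sliding one frame
  per output map — short enough to resolve ring evolution frame by frame,
  long enough that coherent rotation dominates discretization noise. The
  window length is a config knob, not a derived quantity.

## Ring extraction

Cores are strict 8-neighbour local maxima of LAVD inside the mask, claimed
greedily in descending value (row-major tie-break). For each core,
n_levels = 100 evenly spaced levels are scanned downward from the core
value; a level is accepted while its marching-squares contour around the
core is closed, simple, lies entirely inside the mask (contours touching
the chamber wall are treated as open — behaviour at the wall is otherwise
undefined), encloses exactly this core among unassigned cores (a contour
swallowing a second core marks the merger point and stops the descent),
and has convexity deficiency ≤ d_max. The last accepted level is the
outermost boundary. Areas use the shoelace formula on sub-pixel contour
vertices converted to mm; volume = area × slice thickness; rings below
min_area (default 4 pixel areas) are dropped. d_max defaults to 1,
permissive enough to keep tubular but non-convex rings. The rotation sense
uses the time-averaged vorticity over the analysis window, not a single
frame.

## Synthetic scenes

The generator emulates the acquisition the method targets: 25 phases per
cycle, 1.54 mm/pixel, 6 mm slice, VENC 100 cm/s, and one or two coherent
vortices of opposite sense inside a disk "chamber" mask. Rankine
(piecewise-constant vorticity) and Lamb–Oseen (Gaussian vorticity)
profiles are used because both have closed-form vorticity and circular
particle orbits, giving exact LAVD targets; generated speeds are checked
against the VENC bound so phase round-trips would be alias-free, and all
randomness sits behind one integer seed.

Two fixture choices matter for interpreting results:

- The single-vortex LAVD benchmark uses a = 1 (16 px), Γ = π, mask radius
  2, T = 1 s, for which LAVD is exactly 0.75/0.25 rad inside/outside the
  core.
- The two-vortex benchmark uses weak swirl (interior angular velocity
  0.05 s⁻¹, cores of 45 px at 100 px separation) so that each vortex's far
  field displaces the partner's material edge by less than a pixel over
  the window. This keeps the analytic core disk a valid ground-truth
  region for the detected boundary; with strong swirl the detected region
  bulges along streamlines — a real material-transport effect, not an
  extraction artifact.

What the scenes do *not* emulate: chamber-wall geometry and no-slip
boundaries, through-plane motion, phase noise and intravoxel dephasing,
and beat-to-beat variability. Passing tests therefore validate the
numerics and the extraction logic, not clinical performance on scans.

## Evaluation metrics

SSIM uses the canonical constants (11×11 Gaussian window, σ = 1.5,
K₁ = 0.01, K₂ = 0.03, data range from the series' intensity range) with
the local map averaged over the region of interest (masked mean, not a
cropped bounding box). IE is the RMS intensity difference over the ROI on
the 0–255 scale. Dice is 2TP/(2TP + FP + FN), defined as 1 when both
masks are empty. The leave-some-out protocol drops k consecutive interior
frames from every window, resynthesizes them from the flanking frames,
and scores each reconstruction against the held-out original.

## Problem sizes

Default test/validation sizes: 73×73 (single-vortex LAVD, dt = 0.02 s,
~3200 seeds), 225×225 (two-vortex extraction, ~35k seeds), 97×97
(pipeline runs), 64×64 image sequences for flow and interpolation
studies. These resolve the analytic features (16–45 px cores, ≥2 px away
from discontinuities) while keeping a full run in seconds.

## Known limitations

- Single-scale Horn–Schunck: displacements beyond a few pixels per frame
  step are underestimated (no pyramid); the skip-frame experiments show
  the resulting monotone degradation.
- 2D only: rings are planar curves and volumes are single-slice
  extrusions; no 3D tube extraction or ring identity tracking across
  frames.
- No phase unwrapping; aliased inputs are rejected, not corrected.
- Chamber segmentation is an input (manual masks); the pipeline's
  sensitivity to mask choice can be probed via the Dice metric but no
  automatic segmenter is provided.
- The level-scan boundary sits at the lowest accepted contour, so on
  noise-free scenes it lands at the outer foot of the (finite-difference)
  vorticity transition, ~1–2 px outside the true core edge.
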