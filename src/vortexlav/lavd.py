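"""Particle advection and the Lagrangian Averaged Vorticity Deviation.

Fluid particles seeded at x0 follow dx/dt = v(x, t) through the (temporally
interpolated) velocity series; the LAVD of a seed over a window [t0, t1] is
the trajectory integral of the absolute deviation of vorticity from its
instantaneous spatial mean over the analysis domain,

    LAVD(x0) = integral_{t0}^{t1} | omega(x(x0, s), s) - mean_omega(s) | ds,

an objective (frame-invariant) measure of the net material rotation a
particle experiences.  Half the LAVD is the intrinsic rotation angle psi.
Vortex boundaries and cores are then read off the LAVD map (see
:mod:`vortexlav.extract`).

Numerical scheme: vorticity is computed per stored frame by central
differences and interpolated bilinearly in space / linearly in time at
particle positions; trajectories use classical fixed-step RK4; the LAVD
integral uses the trapezoidal rule.  Seeds that leave the image domain are
frozen at exit and stop accumulating; seeds that leave the chamber mask but
stay in-image continue (blood crosses chamber boundaries physically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ChamberMask, ScanGeometry, VelocitySeries


@dataclass
class VorticityField:
    """Scalar 2D vorticity dv/dx - du/dy on the grid, 1/s, at one instant.

    Computed in array coordinates (y down); the conventional y-up vorticity
    is its negative.
    """

    omega: np.ndarray
    time: float = 0.0


@dataclass
class MeanVorticityTrace:
    """Spatial mean of vorticity over the analysis domain, one value per step."""

    values: np.ndarray
    times: np.ndarray
    domain: ChamberMask | None = None


@dataclass
class TrajectorySet:
    """Particle trajectories: positions (n_steps+1, N, 2) in mm (x, y), and
    per-step alive flags (False once a particle has left the image domain)."""

    positions: np.ndarray
    alive: np.ndarray
    times: np.ndarray

    @property
    def initial(self) -> np.ndarray:
        return self.positions[0]

    @property
    def final(self) -> np.ndarray:
        return self.positions[-1]


@dataclass
class LavdMap:
    """LAVD values (rad, >= 0) per seed, on the image grid.

    ``values`` is zero outside the seeded mask; ``psi`` (= LAVD/2) is the
    intrinsic rotation angle.
    """

    values: np.ndarray
    window: tuple[float, float]
    geometry: ScanGeometry
    seed_mask: np.ndarray | None = None

    @property
    def psi(self) -> np.ndarray:
        return 0.5 * self.values


def vorticity(u_frame: np.ndarray, v_frame: np.ndarray, pixel_spacing: float) -> VorticityField:
    """Scalar vorticity dv/dx - du/dy by central differences (one-sided edges)."""
    u_frame = np.asarray(u_frame, dtype=float)
    v_frame = np.asarray(v_frame, dtype=float)
    if u_frame.shape != v_frame.shape:
        raise ValueError("u and v frames must be congruent")
    if min(u_frame.shape) < 3:
        raise ValueError("frames must be at least 3x3")
    if not pixel_spacing > 0:
        raise ValueError("pixel_spacing must be > 0")
    dv_dx = np.gradient(v_frame, pixel_spacing, axis=1)
    du_dy = np.gradient(u_frame, pixel_spacing, axis=0)
    return VorticityField(omega=dv_dx - du_dy)


def mean_vorticity(omega: VorticityField, mask: ChamberMask) -> float:
    """Arithmetic mean of vorticity over the mask pixels."""
    mask.require_nonempty()
    if omega.omega.shape != mask.pixels.shape:
        raise ValueError("vorticity and mask shapes must match")
    return float(omega.omega[mask.pixels].mean())


def _bilinear(frame: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sampling with edge clamping, vectorized over query points."""
    h, w = frame.shape
    r = np.clip(rows, 0.0, h - 1.0)
    c = np.clip(cols, 0.0, w - 1.0)
    r0 = np.clip(np.floor(r).astype(int), 0, h - 2) if h > 1 else np.zeros_like(r, dtype=int)
    c0 = np.clip(np.floor(c).astype(int), 0, w - 2) if w > 1 else np.zeros_like(c, dtype=int)
    fr = r - r0
    fc = c - c0
    f00 = frame[r0, c0]
    f01 = frame[r0, c0 + 1]
    f10 = frame[r0 + 1, c0]
    f11 = frame[r0 + 1, c0 + 1]
    return (f00 * (1 - fr) * (1 - fc) + f01 * (1 - fr) * fc
            + f10 * fr * (1 - fc) + f11 * fr * fc)


def _bracket(times: np.ndarray, t: float) -> tuple[int, int, float]:
    """Indices of the frames bracketing time t and the blend weight."""
    if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
        raise ValueError(f"time {t} outside series span [{times[0]}, {times[-1]}]")
    k = int(np.searchsorted(times, t, side="right") - 1)
    k = min(max(k, 0), len(times) - 2)
    w = (t - times[k]) / (times[k + 1] - times[k])
    return k, k + 1, float(np.clip(w, 0.0, 1.0))


def sample_velocity(series: VelocitySeries, positions: np.ndarray, time: float) -> np.ndarray:
    """Velocity (mm/s) at physical positions (N, 2) = (x, y) mm and a time.

    Bilinear in space on each component, linear in time between the two
    bracketing frames.  Positions outside the grid clamp to the edge value.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    k0, k1, w = _bracket(series.times, time)
    s = series.geometry.pixel_spacing
    cols = positions[:, 0] / s
    rows = positions[:, 1] / s
    out = np.empty_like(positions)
    for j, stack in enumerate((series.u, series.v)):
        v0 = _bilinear(stack[k0], rows, cols)
        v1 = _bilinear(stack[k1], rows, cols)
        out[:, j] = (1 - w) * v0 + w * v1
    return out


def _in_domain(positions: np.ndarray, shape: tuple[int, int], spacing: float) -> np.ndarray:
    h, w = shape
    x, y = positions[:, 0], positions[:, 1]
    return (x >= 0) & (x <= (w - 1) * spacing) & (y >= 0) & (y <= (h - 1) * spacing)


def _time_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    """Step times t0, t0+dt, ..., t1 with the last step shortened to land on t1."""
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if dt > t1 - t0:
        raise ValueError("dt exceeds the integration window")
    n_full = int(np.floor((t1 - t0) / dt - 1e-12))
    times = t0 + dt * np.arange(n_full + 1)
    if times[-1] < t1 - 1e-12:
        times = np.append(times, t1)
    else:
        times[-1] = t1
    return times


def _rk4_step(series: VelocitySeries, pos: np.ndarray, t: float, h: float) -> np.ndarray:
    k1 = sample_velocity(series, pos, t)
    k2 = sample_velocity(series, pos + 0.5 * h * k1, t + 0.5 * h)
    k3 = sample_velocity(series, pos + 0.5 * h * k2, t + 0.5 * h)
    k4 = sample_velocity(series, pos + h * k3, t + h)
    return pos + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def advect(series: VelocitySeries, seeds: np.ndarray, t0: float, t1: float,
           dt: float) -> TrajectorySet:
    """Integrate particle trajectories with classical fixed-step RK4.

    ``seeds`` are (N, 2) physical (x, y) positions in mm.  Particles leaving
    the image domain are frozen at their exit position and flagged not-alive.
    """
    t0_s, t1_s = series.time_span
    if t0 < t0_s - 1e-9 or t1 > t1_s + 1e-9:
        raise ValueError("integration window outside the series time span")
    times = _time_grid(t0, t1, dt)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = len(seeds)
    spacing = series.geometry.pixel_spacing
    shape = series.frame_shape
    positions = np.empty((len(times), n, 2))
    alive = np.empty((len(times), n), dtype=bool)
    pos = seeds.copy()
    live = _in_domain(pos, shape, spacing)
    positions[0] = pos
    alive[0] = live
    for k in range(len(times) - 1):
        h = times[k + 1] - times[k]
        new_pos = _rk4_step(series, pos, times[k], h)
        inside = _in_domain(new_pos, shape, spacing)
        # freeze particles at their last in-domain position
        step_live = live & inside
        pos = np.where((live & inside)[:, None], new_pos, pos)
        live = step_live
        positions[k + 1] = pos
        alive[k + 1] = live
    return TrajectorySet(positions=positions, alive=alive, times=times)


def compute_lavd(series: VelocitySeries, mask: ChamberMask, t0: float, t1: float,
                 dt: float, domain_mask: ChamberMask | None = None) -> LavdMap:
    """LAVD map over the window [t0, t1], seeded at every mask pixel.

    ``domain_mask`` is the (fixed) averaging domain for the spatial-mean
    vorticity; it defaults to the seed mask.  Vorticity is evaluated on the
    stored (possibly synthesized) frames, interpolated at particle positions
    at every RK4 step time, and |omega - mean_omega| is accumulated by the
    trapezoidal rule.  Seeds that leave the image stop accumulating.
    """
    mask.require_nonempty()
    if mask.pixels.shape != series.frame_shape:
        raise ValueError("mask and velocity frames must share a shape")
    domain = domain_mask or mask
    domain.require_nonempty()
    spacing = series.geometry.pixel_spacing

    # per stored frame: vorticity field and its mask-mean (both interpolate
    # linearly in time because the in-between velocity does)
    omegas = np.stack([
        vorticity(series.u[k], series.v[k], spacing).omega for k in range(len(series))
    ])
    omega_means = np.array([float(om[domain.pixels].mean()) for om in omegas])

    def deviation_at(pos: np.ndarray, t: float) -> np.ndarray:
        k0, k1, w = _bracket(series.times, t)
        cols = pos[:, 0] / spacing
        rows = pos[:, 1] / spacing
        om = (1 - w) * _bilinear(omegas[k0], rows, cols) + w * _bilinear(omegas[k1], rows, cols)
        om_bar = (1 - w) * omega_means[k0] + w * omega_means[k1]
        return np.abs(om - om_bar)

    rows, cols = np.nonzero(mask.pixels)
    seeds = np.stack([cols * spacing, rows * spacing], axis=1)
    traj = advect(series, seeds, t0, t1, dt)

    acc = np.zeros(len(seeds))
    prev = deviation_at(traj.positions[0], traj.times[0])
    for k in range(1, len(traj.times)):
        h = traj.times[k] - traj.times[k - 1]
        cur = deviation_at(traj.positions[k], traj.times[k])
        live = traj.alive[k]
        acc[live] += 0.5 * h * (prev[live] + cur[live])
        prev = cur

    values = np.zeros(mask.pixels.shape)
    values[rows, cols] = acc
    return LavdMap(values=values, window=(t0, t1), geometry=series.geometry,
                   seed_mask=mask.pixels.copy())


def mean_vorticity_trace(series: VelocitySeries, mask: ChamberMask) -> MeanVorticityTrace:
    """Per-frame spatial mean vorticity over a fixed mask."""
    mask.require_nonempty()
    spacing = series.geometry.pixel_spacing
    vals = np.array([
        mean_vorticity(vorticity(series.u[k], series.v[k], spacing), mask)
        for k in range(len(series))
    ])
    return MeanVorticityTrace(values=vals, times=series.times.copy(), domain=mask)
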