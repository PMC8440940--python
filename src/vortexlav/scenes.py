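"""Analytic synthetic scenes: vortical velocity fields and moving images.

Real cine phase-contrast data could not be redistributed, so validation
runs on analytic flows that emulate the acquisition: ~25 phases per cardiac
cycle, ~1.54 mm in-plane resolution, 6 mm slice thickness, VENC 100 cm/s,
and swirling flow containing one or two coherent vortices of opposite
sense.  Rankine and Lamb-Oseen vortices are used as fixtures because both
have closed-form vorticity and circular particle orbits, which gives exact
LAVD and ring-boundary targets.

Circulations are specified in the conventional (y-up) sense: positive
circulation means counter-clockwise rotation.  The generated grids follow
the package's array convention (y down), so the stored v-component is the
negative of the conventional one; all consumers account for this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ChamberMask, ImageSeries, ScanGeometry, VelocitySeries

DEFAULT_GEOMETRY = ScanGeometry(
    pixel_spacing=1.54, slice_thickness=6.0, frame_interval=0.04, venc=100.0, n_frames=25
)


@dataclass(frozen=True)
class VortexSpec:
    """One analytic vortex: center (mm), signed circulation (mm^2/s, CCW
    positive in conventional coordinates), core radius (mm), and model."""

    center: tuple[float, float]
    circulation: float
    core_radius: float
    model: str = "rankine"
    drift: tuple[float, float] = (0.0, 0.0)  # center drift, mm/s

    def __post_init__(self) -> None:
        if not self.core_radius > 0:
            raise ValueError("core_radius must be > 0")
        if self.model not in ("rankine", "lamb_oseen"):
            raise ValueError(f"unknown vortex model {self.model!r}")

    @property
    def sense(self) -> str:
        return "CCW" if self.circulation > 0 else "CW"


@dataclass
class SceneSpec:
    """A synthetic flow scene on a (H, W) grid with scan geometry."""

    shape: tuple[int, int]
    geometry: ScanGeometry = DEFAULT_GEOMETRY
    vortices: list[VortexSpec] = field(default_factory=list)
    background: tuple[float, float] = (0.0, 0.0)  # uniform flow, mm/s
    noise_sd: float = 0.0  # additive velocity noise, mm/s
    mask_radius: float | None = None  # mm; default: largest inscribed disk minus margin
    seed: int = 0


@dataclass(frozen=True)
class GroundTruthRing:
    """Analytic truth for one vortex: core center/disk and rotation sense."""

    center: tuple[float, float]
    radius: float
    sense: str
    circulation: float

    def region(self, shape: tuple[int, int], pixel_spacing: float) -> np.ndarray:
        rows, cols = np.indices(shape)
        dx = cols * pixel_spacing - self.center[0]
        dy = rows * pixel_spacing - self.center[1]
        return dx**2 + dy**2 <= self.radius**2


def _angular_factor(r2: np.ndarray, vor: VortexSpec) -> np.ndarray:
    """k(r) = v_theta(r) / r, vectorized on squared radius."""
    gamma, a = vor.circulation, vor.core_radius
    if vor.model == "rankine":
        k_in = gamma / (2.0 * np.pi * a**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            k_out = gamma / (2.0 * np.pi * r2)
        return np.where(r2 < a**2, k_in, k_out)
    # Lamb-Oseen: smooth Gaussian vorticity core
    k0 = gamma / (2.0 * np.pi * a**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = gamma / (2.0 * np.pi * r2) * (1.0 - np.exp(-r2 / a**2))
    return np.where(r2 > 0, k, k0)


def vortex_velocity(x: np.ndarray, y: np.ndarray, vor: VortexSpec,
                    t: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Array-frame velocity components (u, v) of one vortex at time t.

    In array coordinates (y down) a conventional-CCW vortex reads
    u = +k(r) dy, v = -k(r) dx.
    """
    cx = vor.center[0] + vor.drift[0] * t
    cy = vor.center[1] + vor.drift[1] * t
    dx = x - cx
    dy = y - cy
    k = _angular_factor(dx**2 + dy**2, vor)
    return k * dy, -k * dx


def make_velocity_scene(spec: SceneSpec, n_frames: int = 3,
                        frame_interval: float | None = None
                        ) -> tuple[VelocitySeries, ChamberMask, list[GroundTruthRing]]:
    """Sample the analytic scene on the grid for each frame.

    Returns the velocity series, a disk chamber mask covering the scene, and
    the analytic ground-truth ring records (core centers, core disks,
    senses).  All randomness (velocity noise) is governed by ``spec.seed``.
    """
    h, w = spec.shape
    s = spec.geometry.pixel_spacing
    dt = frame_interval if frame_interval is not None else spec.geometry.frame_interval
    extent_x, extent_y = (w - 1) * s, (h - 1) * s
    for vor in spec.vortices:
        cx, cy = vor.center
        if (cx - vor.core_radius < 0 or cx + vor.core_radius > extent_x
                or cy - vor.core_radius < 0 or cy + vor.core_radius > extent_y):
            raise ValueError("vortex core extends beyond the grid")
    rows, cols = np.indices(spec.shape)
    x = cols * s
    y = rows * s
    rng = np.random.default_rng(spec.seed)
    times = np.arange(n_frames) * dt
    u_frames = np.empty((n_frames, h, w))
    v_frames = np.empty((n_frames, h, w))
    for k, t in enumerate(times):
        u = np.full(spec.shape, float(spec.background[0]))
        v = np.full(spec.shape, float(spec.background[1]))
        for vor in spec.vortices:
            du, dv = vortex_velocity(x, y, vor, t)
            u += du
            v += dv
        if spec.noise_sd > 0:
            u += rng.normal(0.0, spec.noise_sd, spec.shape)
            v += rng.normal(0.0, spec.noise_sd, spec.shape)
        u_frames[k] = u
        v_frames[k] = v
    venc_mm_s = spec.geometry.venc * 10.0
    speed = np.hypot(u_frames, v_frames).max()
    if speed > venc_mm_s:
        raise ValueError(
            f"scene speed {speed:.1f} mm/s exceeds the VENC bound {venc_mm_s:.1f} mm/s "
            "(would alias in a phase round-trip)")
    series = VelocitySeries(u=u_frames, v=v_frames, times=times, geometry=spec.geometry)

    center = ((w - 1) / 2.0 * s, (h - 1) / 2.0 * s)
    radius = spec.mask_radius if spec.mask_radius is not None else (min(h, w) / 2.0 - 2.0) * s
    mask_pix = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2
    mask = ChamberMask(pixels=mask_pix, label="synthetic-disk")

    truth = [GroundTruthRing(center=v.center, radius=v.core_radius,
                             sense=v.sense, circulation=v.circulation)
             for v in spec.vortices]
    return series, mask, truth


def _cosine_field(shape: tuple[int, int], rng: np.random.Generator,
                  n_modes: int = 24) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random band-limited pattern as a sum of cosine modes (analytic, so it
    can be evaluated at arbitrarily shifted positions)."""
    amps = rng.uniform(0.5, 1.0, n_modes)
    freqs = rng.uniform(0.02, 0.15, (n_modes, 2)) * 2 * np.pi
    signs = rng.choice([-1.0, 1.0], (n_modes, 2))
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    return amps, freqs * signs, phases


def make_image_sequence(pattern: str = "gaussian_blob",
                        shift_per_frame: tuple[float, float] = (1.0, 0.0),
                        n_frames: int = 8, noise_sd: float = 0.0, seed: int = 0,
                        shape: tuple[int, int] = (64, 64),
                        blob_sigma: float = 6.0) -> ImageSeries:
    """Image sequence of a pattern translating by ``shift_per_frame`` pixels.

    Frame k is the analytic pattern evaluated at x - k * shift (exact
    resampling, no integer shifting), plus seeded Gaussian noise, clipped to
    the 0-255 scale.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if pattern not in ("gaussian_blob", "smoothed_noise"):
        raise ValueError(f"unknown pattern {pattern!r}")
    h, w = shape
    rows, cols = np.indices(shape, dtype=float)
    rng = np.random.default_rng(seed)
    if pattern == "smoothed_noise":
        amps, kvecs, phases = _cosine_field(shape, rng)

    def evaluate_raw(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        if pattern == "gaussian_blob":
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            return np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * blob_sigma**2))
        acc = np.zeros_like(xs)
        for a, (kx, ky), ph in zip(amps, kvecs, phases):
            acc += a * np.cos(kx * xs + ky * ys + ph)
        return acc

    # one shared affine normalization so frames are exact translates
    base = evaluate_raw(cols, rows)
    lo, hi = float(base.min()), float(base.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0

    def evaluate(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        if pattern == "gaussian_blob":
            return 255.0 * evaluate_raw(xs, ys)
        return (evaluate_raw(xs, ys) - lo) * scale

    frames = []
    for k in range(n_frames):
        xs = cols - k * shift_per_frame[0]
        ys = rows - k * shift_per_frame[1]
        frame = evaluate(xs, ys)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, shape)
        frames.append(np.clip(frame, 0.0, 255.0))
    times = np.arange(n_frames, dtype=float)
    return ImageSeries(frames=np.stack(frames), times=times, intensity_range=(0.0, 255.0))
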