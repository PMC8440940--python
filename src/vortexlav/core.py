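"""Core domain types for 2D phase-contrast velocimetry.

All internal quantities use canonical units: lengths in mm, times in s,
velocities in mm/s, angles in rad.  Conversions (VENC phase scaling,
ml for volumes) happen only at the I/O boundaries.

Coordinate convention: grids are indexed ``(row, col)``, 0-based; physical
``x = col * pixel_spacing`` and ``y = row * pixel_spacing`` with y increasing
*downward* in array space.  This frame is left-handed, so the scalar
vorticity dv/dx - du/dy computed in it is the negative of the conventional
(y-up) vorticity; rotation-sense reporting applies the sign correction so
that "CCW" always means counter-clockwise in conventional coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class AliasingError(ValueError):
    """Phase values outside [-pi, pi]: velocity aliasing, not correctable here."""


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of a single-slice cine phase-contrast scan.

    Parameters
    ----------
    pixel_spacing : float
        In-plane resolution, mm/pixel (isotropic).
    slice_thickness : float
        Through-plane resolution, mm.
    frame_interval : float
        Time between reconstructed cardiac phases, s.
    venc : float
        Velocity-encoding limit, cm/s: the speed mapped to phase +/-pi.
    n_frames : int
        Number of cardiac phases per cycle.
    """

    pixel_spacing: float
    slice_thickness: float
    frame_interval: float
    venc: float
    n_frames: int

    def __post_init__(self) -> None:
        for name in ("pixel_spacing", "slice_thickness", "frame_interval", "venc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def times(self) -> np.ndarray:
        """Frame times in s, uniform spacing from 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ChamberMask:
    """Binary segmentation of the cardiac chamber of interest (e.g. the RA)."""

    pixels: np.ndarray
    label: str = "RA"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2D grid")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def require_nonempty(self) -> None:
        if self.n_pixels == 0:
            raise ValueError(f"mask '{self.label}' has no pixels set")


@dataclass
class ImageSeries:
    """Ordered scalar intensity frames I(x, y, t).

    ``frames`` has shape (T, H, W); ``times`` is strictly increasing, in s.
    ``intensity_range`` is the nominal dynamic range of the scale (default
    8-bit), used as the SSIM data range.
    """

    frames: np.ndarray
    times: np.ndarray
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class VelocitySeries:
    """Time series of in-plane velocity fields v(x, t) on a regular grid.

    ``u`` and ``v`` are (T, H, W) stacks of the x- (column) and y- (row)
    velocity components in mm/s.  ``times`` in s, strictly increasing.
    """

    u: np.ndarray
    v: np.ndarray
    times: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v stacks must be congruent")
        if self.u.ndim != 3:
            raise ValueError("velocity stacks must be (T, H, W)")
        if len(self.times) != len(self.u):
            raise ValueError("times and frames length mismatch")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("velocity values must be finite")

    def __len__(self) -> int:
        return len(self.u)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.u.shape[1:]

    @property
    def time_span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class VortexRing:
    """A detected Lagrangian vortex ring on one frame.

    The boundary is the outermost closed, sufficiently convex LAVD level
    curve around the core (an enclosed LAVD local maximum); the volume is
    the enclosed area extruded through the slice thickness.
    """

    boundary: np.ndarray  # (N, 2) closed polygon, (x, y) in mm
    core: tuple[float, float]  # (x, y) mm
    core_lavd: float  # rad
    area: float  # mm^2
    volume: float  # ml
    sense: str  # "CW" | "CCW", conventional y-up coordinates
    level: float  # LAVD contour value, rad
    frame_index: int = 0

    def to_dict(self) -> dict:
        return {
            "frame_index": int(self.frame_index),
            "sense": self.sense,
            "core_x_mm": float(self.core[0]),
            "core_y_mm": float(self.core[1]),
            "core_lavd_rad": float(self.core_lavd),
            "level_rad": float(self.level),
            "area_mm2": float(self.area),
            "volume_ml": float(self.volume),
            "boundary_mm": np.asarray(self.boundary, dtype=float).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VortexRing":
        return cls(
            boundary=np.asarray(d["boundary_mm"], dtype=float),
            core=(d["core_x_mm"], d["core_y_mm"]),
            core_lavd=d["core_lavd_rad"],
            area=d["area_mm2"],
            volume=d["volume_ml"],
            sense=d["sense"],
            level=d["level_rad"],
            frame_index=d["frame_index"],
        )


@dataclass
class RingReport:
    """All rings detected over an analysis, with per-frame volumes and provenance."""

    rings: list[VortexRing] = field(default_factory=list)
    frame_times: dict[int, float] = field(default_factory=dict)
    config_hash: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        for ring in self.rings:
            if ring.volume < 0:
                raise ValueError("ring volumes must be >= 0")

    def volumes_table(self) -> list[dict]:
        """Per-frame volume rows: frame_index, time_s, ring_id, sense, volume_ml."""
        rows = []
        for ring_id, ring in enumerate(self.rings):
            rows.append(
                {
                    "frame_index": int(ring.frame_index),
                    "time_s": float(self.frame_times.get(ring.frame_index, float("nan"))),
                    "ring_id": ring_id,
                    "sense": ring.sense,
                    "volume_ml": float(ring.volume),
                }
            )
        return rows


def phase_to_velocity(phase: np.ndarray, venc: float) -> np.ndarray:
    """Convert velocity-encoded phase (rad) to velocity in mm/s.

    The phase of the MR signal is proportional to velocity along the
    encoding direction; +/-pi maps to +/-VENC.  Phase outside [-pi, pi]
    indicates aliasing and raises :class:`AliasingError` (unwrapping is out
    of scope).

    Parameters
    ----------
    phase : array-like
        Phase image in radians, values in [-pi, pi].
    venc : float
        Velocity-encoding limit in cm/s.

    Returns
    -------
    ndarray
        Velocity in mm/s, same shape; sign preserved.
    """
    if not venc > 0:
        raise ValueError("venc must be strictly positive")
    phase = np.asarray(phase, dtype=float)
    if np.any(np.abs(phase) > np.pi + 1e-12):
        raise AliasingError("phase outside [-pi, pi]: velocity aliasing")
    return phase / np.pi * (venc * 10.0)  # cm/s -> mm/s
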