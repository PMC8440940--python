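"""Vortex-ring extraction from an LAVD map.

A rotationally coherent Lagrangian vortex appears in the LAVD map as a
nested family of outward-decreasing tubular level sets.  The vortex core is
a strict local maximum of LAVD; the ring boundary is the *outermost* closed
LAVD level curve around that core whose convexity deficiency

    d = (area(convex hull) - area(curve)) / area(curve)

stays below a threshold d_max (d = 0 for convex curves).  The ring volume
is the enclosed area extruded through the slice thickness; the rotation
sense is read from the mean vorticity over the enclosed pixels, reported in
conventional (y-up) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import maximum_filter
from shapely.geometry import Polygon
from skimage.measure import find_contours

from .core import ChamberMask, ScanGeometry, VortexRing
from .lavd import LavdMap, VorticityField


class Core(NamedTuple):
    """A candidate vortex core: LAVD local-maximum pixel."""

    row: int
    col: int
    value: float


@dataclass(frozen=True)
class ExtractionParams:
    """Ring-extraction knobs.

    d_max : convexity-deficiency threshold (dimensionless, default 1 —
        permissive enough to keep rings that are tubular but not perfectly
        convex).
    n_levels : number of candidate contour levels scanned downward from each
        core value.
    min_area : smallest accepted ring area in mm^2; None means 4 pixel areas
        at the scan resolution.
    """

    d_max: float = 1.0
    n_levels: int = 100
    min_area: float | None = None

    def __post_init__(self) -> None:
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


def shoelace_area(polygon: np.ndarray) -> float:
    """Absolute polygon area by the shoelace formula; vertices (N, 2)."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def convexity_deficiency(polygon: np.ndarray) -> float:
    """Relative area gap between a closed simple polygon and its convex hull.

    Zero (within floating tolerance) iff the polygon is convex.
    """
    p = np.asarray(polygon, dtype=float)
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    if len(p) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    poly = Polygon(p)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    if poly.area <= 0:
        raise ValueError("polygon must enclose a positive area")
    hull = poly.convex_hull
    return (hull.area - poly.area) / poly.area


def find_cores(lavd: LavdMap, mask: ChamberMask) -> list[Core]:
    """Strict 8-neighborhood local maxima of LAVD inside the mask, LAVD > 0,
    sorted by descending value."""
    values = np.asarray(lavd.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("LAVD map must be finite")
    if values.shape != mask.pixels.shape:
        raise ValueError("LAVD map and mask must share a shape")
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = maximum_filter(values, footprint=footprint, mode="constant", cval=-np.inf)
    is_max = (values > neigh_max) & mask.pixels & (values > 0)
    rows, cols = np.nonzero(is_max)
    cores = [Core(int(r), int(c), float(values[r, c])) for r, c in zip(rows, cols)]
    # descending by value; row-major tie-break keeps the order deterministic
    return sorted(cores, key=lambda c: (-c.value, c.row, c.col))


def ring_volume(area: float, geometry: ScanGeometry) -> float:
    """Ring volume in ml: enclosed area (mm^2) times slice thickness (mm)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return area * geometry.slice_thickness / 1000.0


def region_mask(boundary_mm: np.ndarray, shape: tuple[int, int], pixel_spacing: float) -> np.ndarray:
    """Boolean grid of pixels whose centers lie inside a boundary polygon (mm)."""
    rows, cols = np.indices(shape)
    pts = np.stack([cols.ravel() * pixel_spacing, rows.ravel() * pixel_spacing], axis=1)
    path = MplPath(np.asarray(boundary_mm, dtype=float))
    return path.contains_points(pts).reshape(shape)


def _closed_contours_at(values: np.ndarray, level: float) -> list[np.ndarray]:
    return [c for c in find_contours(values, level) if np.allclose(c[0], c[-1])]


def _contour_in_mask(contour_rc: np.ndarray, mask: np.ndarray) -> bool:
    """True if every contour vertex rounds to an inside-mask pixel (contours
    hugging the chamber wall are treated as open and rejected)."""
    r = np.clip(np.rint(contour_rc[:, 0]).astype(int), 0, mask.shape[0] - 1)
    c = np.clip(np.rint(contour_rc[:, 1]).astype(int), 0, mask.shape[1] - 1)
    return bool(mask[r, c].all())


def extract_rings(lavd: LavdMap, mask: ChamberMask, params: ExtractionParams,
                  vort: VorticityField, geometry: ScanGeometry,
                  frame_index: int = 0) -> list[VortexRing]:
    """Extract vortex rings: one boundary per claimed core.

    Cores are claimed greedily in descending LAVD order.  For each core,
    ``n_levels`` evenly spaced contour levels are scanned downward from the
    core value; a level is accepted while its marching-squares contour around
    the core is closed, simple, stays inside the mask, encloses exactly this
    core among the still-unassigned cores, and has convexity deficiency
    <= d_max.  The last accepted (lowest, hence outermost) contour is the
    ring boundary.  Rings smaller than ``min_area`` are discarded.
    """
    values = np.asarray(lavd.values, dtype=float)
    if values.shape != mask.pixels.shape or values.shape != vort.omega.shape:
        raise ValueError("LAVD, mask and vorticity grids must be congruent")
    spacing = geometry.pixel_spacing
    min_area = params.min_area if params.min_area is not None else 4.0 * spacing**2

    cores = find_cores(lavd, mask)
    unassigned = list(cores)
    rings: list[VortexRing] = []
    floor = float(values.min())

    for core in cores:
        if core not in unassigned:
            continue
        levels = np.linspace(core.value, floor, params.n_levels + 1)[1:]
        best: np.ndarray | None = None
        best_level = np.nan
        for level in levels:
            if level <= floor:
                break
            candidates = []
            for contour in _closed_contours_at(values, level):
                path = MplPath(contour)
                if path.contains_point((core.row, core.col)):
                    candidates.append(contour)
            if not candidates:
                break
            # innermost containing contour: nested level-set components
            contour = min(candidates, key=shoelace_area)
            if not _contour_in_mask(contour, mask.pixels):
                break
            enclosed = [c for c in unassigned
                        if MplPath(contour).contains_point((c.row, c.col))]
            if len(enclosed) != 1 or enclosed[0] != core:
                break  # merger with a neighboring core terminates the descent
            try:
                deficiency = convexity_deficiency(contour)
            except ValueError:
                break  # degenerate / self-intersecting contour
            if deficiency > params.d_max:
                break
            best = contour
            best_level = float(level)
        unassigned.remove(core)
        if best is None:
            continue
        boundary_mm = best[:, ::-1] * spacing  # (row, col) -> (x, y) mm
        area = shoelace_area(boundary_mm)
        if area < min_area:
            continue
        region = region_mask(boundary_mm, values.shape, spacing)
        if not region.any():
            continue
        omega_mean = float(vort.omega[region].mean())
        # array-frame vorticity is the negative of the conventional (y-up) one
        sense = "CCW" if -omega_mean > 0 else "CW"
        rings.append(VortexRing(
            boundary=boundary_mm,
            core=(core.col * spacing, core.row * spacing),
            core_lavd=core.value,
            area=area,
            volume=ring_volume(area, geometry),
            sense=sense,
            level=best_level,
            frame_index=frame_index,
        ))
    return rings
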