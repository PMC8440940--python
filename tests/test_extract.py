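import numpy as np
import pytest

from vortexlav import (ChamberMask, ExtractionParams, ScanGeometry, convexity_deficiency,
                       dice, extract_rings, find_cores, region_mask, ring_volume,
                       shoelace_area, vorticity)
from vortexlav.lavd import LavdMap, VorticityField

GEOMETRY = ScanGeometry(1.0, 6.0, 0.04, 100.0, 25)

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
TRIANGLE = np.array([[0.0, 0.0], [3.0, 0.0], [1.0, 2.0]])
L_HEXAGON = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [1.0, 1.0], [1.0, 2.0], [0.0, 2.0]])


class TestConvexityDeficiency:
    def test_square_is_convex(self):
        assert convexity_deficiency(SQUARE) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_is_convex(self):
        assert convexity_deficiency(TRIANGLE) == pytest.approx(0.0, abs=1e-12)

    def test_l_hexagon(self):
        # hull adds the corner triangle (area 0.5) to the L-shape (area 3):
        # deficiency = (3.5 - 3) / 3 (hull area verified by the shoelace oracle)
        hull_pts = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [1.0, 2.0], [0.0, 2.0]])
        assert shoelace_area(hull_pts) == pytest.approx(3.5)
        assert convexity_deficiency(L_HEXAGON) == pytest.approx(0.5 / 3.0)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            convexity_deficiency(bowtie)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            convexity_deficiency(np.array([[0.0, 0.0], [1.0, 1.0]]))


def _bump_map(shape=(41, 41), centers=((20, 20),), heights=(1.0,), sigma=5.0):
    rows, cols = np.indices(shape, dtype=float)
    values = np.zeros(shape)
    for (cy, cx), h in zip(centers, heights):
        values += h * np.exp(-((cols - cx) ** 2 + (rows - cy) ** 2) / (2 * sigma**2))
    return LavdMap(values=values, window=(0.0, 1.0), geometry=GEOMETRY)


class TestFindCores:
    def test_flat_map_no_cores(self):
        lavd = LavdMap(values=np.zeros((21, 21)), window=(0, 1), geometry=GEOMETRY)
        assert find_cores(lavd, ChamberMask(np.ones((21, 21), bool))) == []

    def test_single_bump_peak_pixel(self):
        lavd = _bump_map()
        cores = find_cores(lavd, ChamberMask(np.ones((41, 41), bool)))
        assert len(cores) == 1
        assert (cores[0].row, cores[0].col) == tuple(
            np.unravel_index(np.argmax(lavd.values), lavd.values.shape))

    def test_two_bumps_sorted_by_height(self):
        lavd = _bump_map(centers=((12, 12), (30, 30)), heights=(0.5, 1.0), sigma=3.0)
        cores = find_cores(lavd, ChamberMask(np.ones((41, 41), bool)))
        assert len(cores) == 2
        assert (cores[0].row, cores[0].col) == (30, 30)
        assert cores[0].value > cores[1].value


class TestRingVolume:
    @pytest.mark.parametrize("area, expected_ml", [
        (0.0, 0.0),
        (100 * 1.54**2, 1.42296),  # 100 pixels at 1.54 mm/px, 6 mm slice
        (1000.0, 6.0),
    ])
    def test_arithmetic(self, area, expected_ml):
        geo = ScanGeometry(1.54, 6.0, 0.04, 100.0, 25)
        assert ring_volume(area, geo) == pytest.approx(expected_ml)

    def test_negative_area(self):
        with pytest.raises(ValueError):
            ring_volume(-1.0, GEOMETRY)


class TestExtractRings:
    def test_flat_map_no_rings(self):
        lavd = LavdMap(values=np.zeros((21, 21)), window=(0, 1), geometry=GEOMETRY)
        mask = ChamberMask(np.ones((21, 21), bool))
        rings = extract_rings(lavd, mask, ExtractionParams(),
                              VorticityField(np.zeros((21, 21))), GEOMETRY)
        assert rings == []

    def test_radial_bump_gives_near_circular_ring(self):
        lavd = _bump_map(shape=(61, 61), centers=((30, 30),), sigma=8.0)
        mask = ChamberMask(np.ones((61, 61), bool))
        rings = extract_rings(lavd, mask, ExtractionParams(),
                              VorticityField(np.full((61, 61), -1.0)), GEOMETRY)
        assert len(rings) == 1
        ring = rings[0]
        assert convexity_deficiency(ring.boundary) < 0.05
        assert ring.core == pytest.approx((30.0, 30.0))
        assert ring.sense == "CCW"  # array-frame omega < 0 means conventional CCW
        assert ring.volume == pytest.approx(ring.area * 6.0 / 1000.0)

    def test_two_vortex_scene_senses_and_dice(self, two_vortex_scene):
        from vortexlav import compute_lavd
        series, mask, truth = two_vortex_scene
        lavd = compute_lavd(series, mask, 0.0, 1.0, 0.02)
        omega = vorticity(series.u[0], series.v[0], 1.0).omega
        rings = extract_rings(lavd, mask, ExtractionParams(),
                              VorticityField(omega), series.geometry)
        assert len(rings) == 2
        shape = mask.pixels.shape
        matched_senses = set()
        for ring in rings:
            detected = region_mask(ring.boundary, shape, 1.0)
            scores = [dice(ChamberMask(detected), ChamberMask(t.region(shape, 1.0)))
                      for t in truth]
            best = int(np.argmax(scores))
            assert scores[best] >= 0.95
            assert ring.sense == truth[best].sense
            matched_senses.add(ring.sense)
            assert convexity_deficiency(ring.boundary) <= 1.0
        assert matched_senses == {"CW", "CCW"}

    def test_boundaries_do_not_cross(self, two_vortex_scene):
        from shapely.geometry import Polygon

        from vortexlav import compute_lavd
        series, mask, _ = two_vortex_scene
        lavd = compute_lavd(series, mask, 0.0, 1.0, 0.05)
        omega = vorticity(series.u[0], series.v[0], 1.0).omega
        rings = extract_rings(lavd, mask, ExtractionParams(),
                              VorticityField(omega), series.geometry)
        polys = [Polygon(r.boundary) for r in rings]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert not polys[i].boundary.crosses(polys[j].boundary)

    def test_decreasing_dmax_never_grows_rings(self):
        # a crescent-shaped map: stricter convexity can only shrink the boundary
        rows, cols = np.indices((61, 61), dtype=float)
        r = np.hypot(cols - 30, rows - 30)
        values = np.exp(-((r - 8) ** 2) / 18.0) + 1.5 * np.exp(
            -((cols - 30) ** 2 + (rows - 22) ** 2) / 30.0)
        lavd = LavdMap(values=values, window=(0, 1), geometry=GEOMETRY)
        mask = ChamberMask(np.ones((61, 61), bool))
        vort = VorticityField(np.full((61, 61), -1.0))
        areas = []
        for d_max in (1.0, 0.5, 0.1, 0.02):
            rings = extract_rings(lavd, mask, ExtractionParams(d_max=d_max), vort, GEOMETRY)
            areas.append(max((ring.area for ring in rings), default=0.0))
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_every_boundary_satisfies_dmax_and_encloses_core(self, two_vortex_scene):
        from matplotlib.path import Path

        from vortexlav import compute_lavd
        series, mask, _ = two_vortex_scene
        lavd = compute_lavd(series, mask, 0.0, 1.0, 0.05)
        omega = vorticity(series.u[0], series.v[0], 1.0).omega
        params = ExtractionParams(d_max=0.3)
        rings = extract_rings(lavd, mask, params, VorticityField(omega), series.geometry)
        assert rings
        for ring in rings:
            assert convexity_deficiency(ring.boundary) <= params.d_max + 1e-9
            assert Path(ring.boundary).contains_point(ring.core)
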