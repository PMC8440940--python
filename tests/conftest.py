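import numpy as np
import pytest

from vortexlav import ChamberMask, ScanGeometry, VelocitySeries
from vortexlav.scenes import SceneSpec, VortexSpec, make_image_sequence, make_velocity_scene


@pytest.fixture(scope="session")
def rankine_scene():
    """Steady Rankine vortex, core a = 1 (16 px), circulation pi, centered in a
    disk mask of radius 2: the closed-form LAVD over T = 1 s is 0.75 rad on the
    interior plateau and 0.25 rad outside the core (mean vorticity 0.25 /s)."""
    s = 1.0 / 16.0
    h = w = 73
    geometry = ScanGeometry(pixel_spacing=s, slice_thickness=6.0,
                            frame_interval=0.5, venc=100.0, n_frames=3)
    center = ((w - 1) / 2 * s, (h - 1) / 2 * s)
    spec = SceneSpec(shape=(h, w), geometry=geometry,
                     vortices=[VortexSpec(center=center, circulation=np.pi, core_radius=1.0)],
                     mask_radius=2.0)
    series, mask, truth = make_velocity_scene(spec, n_frames=3, frame_interval=0.5)
    return series, mask, truth, center


@pytest.fixture(scope="session")
def two_vortex_scene():
    """Counter-rotating Rankine pair with weak swirl (interior angular velocity
    0.05 /s), so each vortex's far field displaces the partner's material edge
    by under a pixel over the 1 s window and the analytic core disks remain a
    valid ground truth for the detected ring regions."""
    s = 1.0
    h = w = 225
    a = 45.0
    k_in = 0.05  # interior angular velocity, 1/s
    geometry = ScanGeometry(pixel_spacing=s, slice_thickness=6.0,
                            frame_interval=0.5, venc=100.0, n_frames=3)
    gamma = 2 * np.pi * a**2 * k_in
    spec = SceneSpec(shape=(h, w), geometry=geometry, vortices=[
        VortexSpec(center=(62.0, 112.0), circulation=+gamma, core_radius=a),
        VortexSpec(center=(162.0, 112.0), circulation=-gamma, core_radius=a),
    ], mask_radius=105.0)
    series, mask, truth = make_velocity_scene(spec, n_frames=3, frame_interval=0.5)
    return series, mask, truth


@pytest.fixture(scope="session")
def blob_sequence():
    """Gaussian blob translating 1 px/frame: the workhorse for flow recovery
    and leave-some-out interpolation experiments."""
    return make_image_sequence("gaussian_blob", shift_per_frame=(1.0, 0.0),
                               n_frames=8, shape=(64, 64), blob_sigma=6.0)


@pytest.fixture
def full_roi():
    return ChamberMask(np.ones((64, 64), dtype=bool), label="full")


def rigid_rotation_series(omega: float, shape=(65, 65), spacing=0.1,
                          n_frames=3, frame_interval=0.5):
    """Solid-body rotation (conventional CCW for omega > 0) about the grid center."""
    h, w = shape
    geometry = ScanGeometry(pixel_spacing=spacing, slice_thickness=6.0,
                            frame_interval=frame_interval, venc=100.0, n_frames=n_frames)
    rows, cols = np.indices(shape)
    x = cols * spacing
    y = rows * spacing
    cx, cy = (w - 1) / 2 * spacing, (h - 1) / 2 * spacing
    u = omega * (y - cy)
    v = -omega * (x - cx)
    times = np.arange(n_frames) * frame_interval
    return VelocitySeries(u=np.stack([u] * n_frames), v=np.stack([v] * n_frames),
                          times=times, geometry=geometry), (cx, cy)
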