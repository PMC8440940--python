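"""Run the full pipeline on a counter-rotating vortex pair.

Builds a two-vortex scene, upsamples it in time with flow-warped synthesis,
computes LAVD over a sliding window and extracts the two vortex rings with
their boundaries, rotation senses and volumes.
"""

import numpy as np

from vortexlav import (ExtractionParams, PipelineConfig, ScanGeometry,
                       SynthesisParams, run_pipeline)
from vortexlav.scenes import SceneSpec, VortexSpec, make_velocity_scene

geometry = ScanGeometry(pixel_spacing=1.0, slice_thickness=6.0,
                        frame_interval=0.5, venc=100.0, n_frames=3)
a = 18.0
gamma = 2 * np.pi * a**2 * 0.05  # weak swirl: interior angular velocity 0.05 /s
spec = SceneSpec(shape=(97, 97), geometry=geometry, mask_radius=45.0, vortices=[
    VortexSpec(center=(26.0, 48.0), circulation=+gamma, core_radius=a),
    VortexSpec(center=(70.0, 48.0), circulation=-gamma, core_radius=a)])
series, mask, truth = make_velocity_scene(spec, n_frames=3, frame_interval=0.5)

config = PipelineConfig(series=series, mask=mask,
                        synthesis=SynthesisParams(factor=2, method="hs_warp"),
                        extraction=ExtractionParams(d_max=1.0),
                        window_frames=2, output_dir="scratch/ring_demo",
                        save_overlays=True)
report = run_pipeline(config)

print(f"detected {len(report.rings)} ring(s):")
for ring in report.rings:
    print(f"  sense {ring.sense}  core ({ring.core[0]:.1f}, {ring.core[1]:.1f}) mm"
          f"  area {ring.area:7.1f} mm^2  volume {ring.volume:.3f} ml")
print("\ntruth senses:", [t.sense for t in truth],
      "at centers", [t.center for t in truth])
print("Each ring volume is the enclosed area times the 6 mm slice thickness;")
print("an overlay figure is written to scratch/ring_demo/overlay_000.png.")
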