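"""Convert velocity-encoded phase images to velocities.

A phase-contrast scan encodes velocity in the signal phase: +/-pi maps to
+/-VENC (here 100 cm/s).  The conversion is linear and sign-preserving.
"""

import numpy as np

from vortexlav import phase_to_velocity

phase = np.array([np.pi, np.pi / 2, 0.0, -np.pi / 2, -np.pi])
velocity = phase_to_velocity(phase, venc=100.0)

for p, v in zip(phase, velocity):
    print(f"phase {p:+.4f} rad  ->  {v:+8.1f} mm/s")
print("\nphase pi is exactly +VENC (1000 mm/s); the map is odd and linear.")
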