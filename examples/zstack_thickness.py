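"""Biofilm thickness and maximum-intensity projection from a confocal stack.

Builds a small synthetic z-stack whose mean-intensity profile dips at the
substrate interface and above the colony surface, computes the thickness
as the z-distance between the two lowest profile minima, and projects the
stack to 2-D by per-pixel maximum.
"""

import numpy as np

from colonychannels import (
    Calibration,
    Image2D,
    ZStack,
    biofilm_thickness,
    max_intensity_projection,
)

z_step = 3.0  # um between slices
n_slices = 41
cal = Calibration(pixel_size_um=1.0, z_step_um=z_step)

# bright biofilm between slices 5 and 35, moderate background outside, and
# dark bands at the two interfaces — the profile minima that bound the film
rng = np.random.default_rng(0)
slices = []
for z in range(n_slices):
    level = 60.0
    if 5 <= z <= 35:
        level += 90.0 * np.sin(np.pi * (z - 5) / 30.0)
    level -= 45.0 * (np.exp(-((z - 5) ** 2) / 2.0) + np.exp(-((z - 35) ** 2) / 2.0))
    frame = rng.normal(level, 2.0, size=(32, 32)).clip(0, 255)
    slices.append(Image2D(frame.astype(np.uint8), cal))

stack = ZStack(slices)
thickness = biofilm_thickness(stack)
print(f"thickness: {thickness:.0f} um "
      f"(biofilm spans slices 5-35, i.e. {30 * z_step:.0f} um)")

mip = max_intensity_projection(stack)
print(f"projection: {mip.shape[0]}x{mip.shape[1]} px, "
      f"max {mip.pixels.max()}, mean {mip.pixels.mean():.1f}")
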