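"""Color segmentation of a VH-IVUS-style cross-section image.

Renders a known phantom with the display palette, then recovers the
label grid from the image alone by k-means color clustering plus
flood-fill separation of lumen and perivascular background.  On a
noiseless rendering the recovery is exact.
"""

import numpy as np

import dcbsim as d
from dcbsim.parameters import LABEL_NAMES

truth = d.make_heterogeneous_phantom(d.scenarios.ref_phantom_spec(seed=3))
image = d.render_labels(truth)                 # (H, W, 3) uint8
grid = d.segment_image(image, pixel_size=truth.pixel_size, seed=0)

exact = np.array_equal(grid.labels, truth.labels)
print(f"image {image.shape[0]}x{image.shape[1]}, "
      f"recovered == constructed: {exact}")
print("recovered area fractions over tissue pixels:")
for lab, f in sorted(grid.fractions().items()):
    print(f"  {LABEL_NAMES[lab]:>4s}: {100 * f:5.2f} %")
print("Each tissue class keeps its reference display color, so the "
      "k-means centroids map one-to-one onto the palette; lumen and "
      "background are both dark and are separated spatially, not by "
      "color.")
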