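"""Retinal radial vascular expansion and vascular density.

The radial expansion of the developing superficial plexus is half the mean
axis length of the smallest oval enclosing the collagen IV-positive area;
density relates that area to the disc of the expansion radius:
density = area / (expansion^2 * pi).
"""

import numpy as np
from skimage import draw

from hyaloquant import build_vessel_mask
from hyaloquant.retina_metrics import retina_metrics
from hyaloquant.synthetic import ImageSimSpec, generate_flatmount
from hyaloquant.types import FlatmountImage

# a synthetic plexus: use the collagen IV-like footprint of a vessel network
image, truth = generate_flatmount(ImageSimSpec(seed=2))
collagen = np.where(truth.footprint, 180.0, 8.0)
metrics = retina_metrics(
    build_vessel_mask(FlatmountImage({"ColIV": collagen}, 1.0), "ColIV")
)
print(f"plexus:   area {metrics.vascular_area_um2:.0f} um^2, "
      f"radial expansion {metrics.radial_expansion_um:.1f} um, "
      f"density {metrics.density:.3f}")

# sanity case with a known answer: a fully positive disc of radius 100 um
disc = np.zeros((260, 260))
rr, cc = draw.disk((130, 130), 100)
disc[rr, cc] = 180.0
m = retina_metrics(build_vessel_mask(FlatmountImage({"ColIV": disc}, 1.0), "ColIV"))
print(f"disc r=100: expansion {m.radial_expansion_um:.1f} um (expect 100), "
      f"density {m.density:.3f} (expect 1.0)")
# density near 1 means the plexus fills its enclosing oval; sparse networks
# give low density even when the expansion (radial outgrowth) is normal.
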