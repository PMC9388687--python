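"""Quantify channel crosstalk with the contribution statistic.

Builds two spatially disjoint structures, injects a known 8% photon
spillover from the home channel into the neighbor, and shows that the
contribution statistic (bleed-through normalized by the ratio of the
channels' 99th intensity percentiles) recovers the injected fraction.
"""

import numpy as np

import phasorsted as ps
from phasorsted.instrument import DyeSpec
from phasorsted.scenes import Scene, Structure

rng = np.random.default_rng(0)
size, wslab = 128, 57
n = int(0.12 * size * wslab)
pos = np.stack([rng.uniform(2, size - 2, n), rng.uniform(2, wslab, n)], 1)
mirrored = pos.copy()
mirrored[:, 1] = size - 1 - mirrored[:, 1]
dye = DyeSpec("d", [2.5], [1.0], brightness=30.0)
scene = Scene((size, size),
              [Structure("home", pos, dye, 0),
               Structure("neighbor", mirrored, dye, 0)],
              np.zeros((size, size)), np.zeros((size, size)), seed=0)

lam = ps.expected_intensity(scene, 0)
home = rng.poisson(lam["home"]).astype(float)
true_spill = 0.08
neighbor = rng.poisson(lam["neighbor"]).astype(float) \
    + rng.binomial(home.astype(int), true_spill)

r = ps.contribution_pair(home, neighbor, high_pct=97, low_pct=60)
print(f"injected spillover:  {true_spill:.3f}")
print(f"bleed-through:       {r['bleed_through']:.3f}  "
      "(neighbor/home intensity over the home-only ROI)")
print(f"contribution:        {r['contribution']:.3f}  "
      "(bleed-through x P99 ratio; comparable across stainings)")
print(f"ROI size:            {r['roi_pixel_count']} pixels")
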