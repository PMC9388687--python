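"""Estimate resolution by Fourier ring correlation (FRC).

Simulates the same scene in confocal and STED mode, splits each image's
photons binomially into two independent halves, and reads the resolution
as the inverse spatial frequency where the ring-wise correlation of the
two halves first drops below 1/7.  STED should improve resolution by
roughly 2-3x.
"""

import phasorsted as ps

scene = ps.build_scene("five_color", 256, seed=1)
results = {}
for mode, power in (("confocal", 0.0), ("sted", 1.5)):
    img = ps.simulate_channel(scene, 1, mode=mode, sted_power=power, seed=2)
    half_a, half_b = ps.split_photons(img, seed=11)
    frc = ps.frc_curve(half_a.intensity, half_b.intensity,
                       pixel_size=img.instrument.pixel_size)
    results[mode] = frc.resolution
    print(f"{mode:>9}: FRC resolution {frc.resolution:6.1f} nm "
          f"({img.intensity.sum():,} photons)")

print(f"resolution improvement: {results['confocal'] / results['sted']:.2f}x "
      "(donut depletion shrinks the effective PSF)")
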