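"""Hit-vs-blank radial profiles and the signal resolution limit.

Averages simulated hit and blank frames radially and finds the outermost
radius where hits stay consistently above blanks — the radius to which
the sample demonstrably contributes signal (here set by a simulated
post-sample aperture).
"""

import numpy as np

import spidiff as sp
from spidiff.simulator import detector_mask

rng = np.random.default_rng(3)
geom = sp.back_detector(256, 256)
config = sp.ShotConfig()
mask = detector_mask(geom, config)
pm = sp.build_pixel_map(geom)

APERTURE_PX = 70.0
BG_RATE = 0.01
signal = sp.sphere_expected_photons(sp.SphereModel(71.0), 5e11, pm)
signal = np.where(pm.r_px > APERTURE_PX, 0.0, signal) + BG_RATE

mean_hit = rng.poisson(signal, size=(100, *signal.shape)).mean(axis=0)
mean_blank = rng.poisson(BG_RATE, size=(100, *signal.shape)).mean(axis=0)

hit_prof = sp.radial_average(mean_hit, pm, mask=mask)
blank_prof = sp.radial_average(mean_blank, pm, mask=mask)
radius, resolution = sp.signal_resolution_limit(hit_prof, blank_prof,
                                                geom=geom)
print(f"aperture injected at:   {APERTURE_PX:.0f} px")
print(f"signal limit recovered: {radius:.0f} px "
      f"({resolution / 10:.1f} nm half-period resolution)")

# The recovered limit tracks the injected aperture to a pixel or two: the
# hit average rides above the blank average out to that radius and the two
# profiles are statistically identical beyond it.
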