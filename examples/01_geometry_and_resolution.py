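"""Detector geometry: mapping pixel radii to scattering resolution.

Builds the two detector geometries of a tandem single-particle imaging
setup (a wide-angle detector 217.4 mm downstream, a small-angle detector
at 2.4 m; 110 um pixels, 7 keV photons) and converts between pixel radius
and half-period resolution d = lambda / (2 sin alpha).
"""

import spidiff as sp

front = sp.front_detector()
back = sp.back_detector()

lam = sp.wavelength_from_energy(7.0)
print(f"wavelength at 7 keV:          {lam:.4f} A")

r = sp.resolution_to_radius(6.67, front)
print(f"radius at 6.67 A (front):     {r:.1f} px (rounds to {round(r)})")
print(f"resolution at 265 px (front): {sp.radius_to_resolution(265, front):.3f} A")

edge = sp.radius_to_resolution(128, back)
print(f"resolution at 128 px (back):  {edge / 10:.1f} nm")

# The first two lines say the wide-angle detector's useful field (out to
# 265 px) reaches 6.67 A half-period resolution; the last line shows the
# small-angle detector only resolves ~10 nm features - it sees particle
# size and shape, not internal structure.
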