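"""Hit finding, radial averaging, and the hit-vs-blank resolution limit.

Whether a wide-angle detector records genuine particle scattering is not
visible in any single weak frame; it shows up statistically, as radial
average photon counts of hit frames staying consistently above those of
blank frames out to some radius.  The outer edge of the last sustained
excess marks the resolution to which the sample contributes signal (in the
experiment this cutoff is set by the angular acceptance of a post-sample
aperture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import PhotonFrame
from .errors import IncompatibleProfilesError
from .geometry import DetectorGeometry, PixelMap, radius_to_resolution

__all__ = [
    "RadialProfile",
    "find_hits",
    "radial_average",
    "signal_resolution_limit",
    "center_of_intensity",
]


@dataclass
class RadialProfile:
    """Annular mean photon counts: contiguous half-open bins [lo, hi)."""

    bin_lo: np.ndarray       #: pixels
    bin_hi: np.ndarray       #: pixels
    mean: np.ndarray         #: mean photons per pixel per bin (NaN for empty bins)
    n_pixels: np.ndarray     #: unmasked pixels per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_lo + self.bin_hi)

    def resolution(self, geom: DetectorGeometry) -> np.ndarray:
        """Half-period resolution (Angstrom) at each bin centre."""
        return np.array([radius_to_resolution(r, geom) for r in self.bin_centers])

    def compatible_with(self, other: "RadialProfile") -> bool:
        return (self.bin_lo.shape == other.bin_lo.shape
                and np.allclose(self.bin_lo, other.bin_lo)
                and np.allclose(self.bin_hi, other.bin_hi))


def _counts_and_mask(frame) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(frame, PhotonFrame):
        return frame.counts, frame.mask
    return np.asarray(frame), None


def find_hits(frames, lit_threshold: int = 1, min_lit_pixels: int = 50,
              mask: np.ndarray | None = None) -> np.ndarray:
    """Lit-pixel hit finder.

    A frame is a hit iff at least ``min_lit_pixels`` unmasked pixels carry
    ``lit_threshold`` photons or more.  Both comparisons are inclusive.
    """
    out = []
    for frame in frames:
        counts, fmask = _counts_and_mask(frame)
        use = np.ones(counts.shape, bool)
        if fmask is not None:
            use &= ~fmask
        if mask is not None:
            use &= ~np.asarray(mask, bool)
        out.append(int(np.count_nonzero(counts[use] >= lit_threshold))
                   >= min_lit_pixels)
    return np.array(out, dtype=bool)


def radial_average(frame, pmap: PixelMap, mask: np.ndarray | None = None,
                   bin_width: float = 1.0) -> RadialProfile:
    """Azimuthal mean photon count per annulus around the beam centre.

    Annulus membership is by pixel-centre radius in half-open bins
    ``[i*w, (i+1)*w)``.  Empty bins get NaN means.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts, fmask = _counts_and_mask(frame)
    use = np.ones(counts.shape, bool)
    if fmask is not None:
        use &= ~fmask
    if mask is not None:
        use &= ~np.asarray(mask, bool)
    r = pmap.r_px[use]
    idx = np.floor(r / bin_width).astype(int)
    n_bins = int(idx.max()) + 1 if idx.size else 0
    npix = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=counts[use].astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(npix > 0, sums / np.maximum(npix, 1), np.nan)
    edges = np.arange(n_bins + 1) * bin_width
    return RadialProfile(bin_lo=edges[:-1], bin_hi=edges[1:], mean=mean,
                         n_pixels=npix)


def signal_resolution_limit(hit_profile: RadialProfile,
                            blank_profile: RadialProfile,
                            geom: DetectorGeometry | None = None,
                            excess_factor: float = 1.2,
                            run_length: int = 3) -> tuple[float, float] | None:
    """Outermost radius of sustained hit-over-blank excess.

    Scans for runs of at least ``run_length`` consecutive bins where the
    hit mean exceeds ``excess_factor`` times the blank mean; returns the
    outer edge (pixels) of the last bin of the last such run, together
    with the corresponding resolution in Angstrom (NaN if no geometry is
    given), or ``None`` when no qualifying run exists.
    """
    if not hit_profile.compatible_with(blank_profile):
        raise IncompatibleProfilesError("profiles are binned differently")
    with np.errstate(invalid="ignore"):
        elevated = hit_profile.mean > excess_factor * blank_profile.mean
    elevated &= np.isfinite(hit_profile.mean) & np.isfinite(blank_profile.mean)

    last_end = None
    run = 0
    for i, flag in enumerate(elevated):
        run = run + 1 if flag else 0
        if run >= run_length:
            last_end = i
    if last_end is None:
        return None
    radius = float(hit_profile.bin_hi[last_end])
    resolution = radius_to_resolution(radius, geom) if geom is not None else float("nan")
    return radius, resolution


def center_of_intensity(frame, mask: np.ndarray | None = None) -> tuple[float, float]:
    """Photon-weighted mean (row, col) position — a cheap beam-centre refiner."""
    counts, fmask = _counts_and_mask(frame)
    use = np.ones(counts.shape, bool)
    if fmask is not None:
        use &= ~fmask
    if mask is not None:
        use &= ~np.asarray(mask, bool)
    w = np.where(use, counts.astype(float), 0.0)
    total = w.sum()
    if total == 0:
        raise ValueError("no photons: centre of intensity undefined")
    rows = np.arange(counts.shape[0])[:, None]
    cols = np.arange(counts.shape[1])[None, :]
    return float((w * rows).sum() / total), float((w * cols).sum() / total)
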