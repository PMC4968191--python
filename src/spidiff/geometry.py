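"""Detector geometry and reciprocal-space mapping.

A flat pixel-array detector a distance ``L`` downstream of the interaction
point sees elastic scattering at the full scattering angle
``alpha = atan(r / L)`` for a pixel at radius ``r`` from the point where the
forward beam intersects the detector plane.  The momentum-transfer magnitude
is ``q = (4 pi / lambda) sin(alpha / 2)`` and the half-period (speckle)
resolution is ``d = lambda / (2 sin alpha)`` — the convention used throughout
coherent diffractive imaging, where one speckle corresponds to one
half-period of the largest real-space feature.

Units follow small-angle-scattering practice: pixel size in micrometres,
camera length in millimetres, photon energy in keV, wavelength and
resolution in Angstrom, momentum transfer in inverse Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidGeometryError, ResolutionUnreachableError

__all__ = [
    "HC_KEV_ANGSTROM",
    "DetectorGeometry",
    "PixelMap",
    "wavelength_from_energy",
    "build_pixel_map",
    "resolution_to_radius",
    "radius_to_resolution",
]

#: Planck constant times speed of light, in keV * Angstrom.
HC_KEV_ANGSTROM = 12.3984


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in Angstrom for a photon energy in keV.

    Raises
    ------
    InvalidGeometryError
        If the energy is not strictly positive.
    """
    if not energy_kev > 0:
        raise InvalidGeometryError(f"photon energy must be > 0 keV, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat monolithic pixel-grid detector.

    Parameters
    ----------
    n_rows, n_cols
        Pixel counts along the slow and fast axes.
    pixel_size
        Pixel pitch in micrometres.
    distance
        Sample-to-detector distance in millimetres.
    beam_center
        Real-valued (row, col) pixel coordinates of the forward-beam
        intersection.  Pixel centres sit at integer coordinates; the beam
        centre may lie outside the pixel grid (offset detectors).
    photon_energy
        Photon energy in keV.
    """

    n_rows: int
    n_cols: int
    pixel_size: float
    distance: float
    beam_center: tuple[float, float]
    photon_energy: float

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise InvalidGeometryError("pixel counts must be strictly positive")
        for name in ("pixel_size", "distance", "photon_energy"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if len(self.beam_center) != 2:
            raise InvalidGeometryError("beam_center must be a (row, col) pair")

    @property
    def wavelength(self) -> float:
        """Wavelength in Angstrom (derived from photon energy)."""
        return wavelength_from_energy(self.photon_energy)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- structured-text config -------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "DetectorGeometry":
        try:
            return cls(
                n_rows=int(cfg["n_rows"]),
                n_cols=int(cfg["n_cols"]),
                pixel_size=float(cfg["pixel_size_um"]),
                distance=float(cfg["distance_mm"]),
                beam_center=tuple(float(v) for v in cfg["beam_center"]),
                photon_energy=float(cfg["photon_energy_keV"]),
            )
        except KeyError as exc:  # missing key
            raise InvalidGeometryError(f"geometry config missing key {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pixel_size_um": self.pixel_size,
            "distance_mm": self.distance,
            "beam_center": list(self.beam_center),
            "photon_energy_keV": self.photon_energy,
        }


def front_detector(n_rows: int = 512, n_cols: int = 512,
                   beam_center: tuple[float, float] | None = None) -> DetectorGeometry:
    """Wide-angle detector geometry: 217.4 mm camera length, 110 um pixels, 7 keV."""
    if beam_center is None:
        beam_center = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    return DetectorGeometry(n_rows, n_cols, 110.0, 217.4, beam_center, 7.0)


def back_detector(n_rows: int = 256, n_cols: int = 256,
                  beam_center: tuple[float, float] | None = None) -> DetectorGeometry:
    """Small-angle detector geometry: 2.4 m camera length, 110 um pixels, 7 keV."""
    if beam_center is None:
        beam_center = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    return DetectorGeometry(n_rows, n_cols, 110.0, 2400.0, beam_center, 7.0)


@dataclass
class PixelMap:
    """Per-pixel reciprocal-space quantities derived from a geometry.

    ``d`` is +inf at the exact beam centre (forward beam carries no
    resolution information); every other unmasked pixel has finite values.
    """

    geometry: DetectorGeometry
    r_px: np.ndarray        #: radius from beam centre, pixels
    r_mm: np.ndarray        #: radius from beam centre, mm
    alpha: np.ndarray       #: full scattering angle, rad
    q: np.ndarray           #: momentum transfer |q| = (4 pi / lambda) sin(alpha/2), 1/A
    d: np.ndarray           #: half-period resolution lambda / (2 sin alpha), A
    valid: np.ndarray = field(default=None)  #: True where the pixel is usable

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.r_px.shape, dtype=bool)


def build_pixel_map(geom: DetectorGeometry, mask: np.ndarray | None = None) -> PixelMap:
    """Compute per-pixel radius, scattering angle, q and resolution.

    Parameters
    ----------
    geom
        Detector geometry.
    mask
        Optional boolean bad-pixel mask (True = bad); inverted into the
        map's ``valid`` field.
    """
    lam = geom.wavelength
    rows = np.arange(geom.n_rows, dtype=float)[:, None]
    cols = np.arange(geom.n_cols, dtype=float)[None, :]
    dy = rows - geom.beam_center[0]
    dx = cols - geom.beam_center[1]
    r_px = np.hypot(dy, dx)
    r_mm = r_px * geom.pixel_size * 1e-3
    alpha = np.arctan2(r_mm, geom.distance)
    q = (4.0 * np.pi / lam) * np.sin(alpha / 2.0)
    with np.errstate(divide="ignore"):
        d = lam / (2.0 * np.sin(alpha))
    valid = None if mask is None else ~np.asarray(mask, dtype=bool)
    return PixelMap(geometry=geom, r_px=r_px, r_mm=r_mm, alpha=alpha, q=q, d=d,
                    valid=valid)


def resolution_to_radius(d: float, geom: DetectorGeometry) -> float:
    """Pixel radius at which the half-period resolution equals ``d``.

    Inverse of :func:`radius_to_resolution`:
    ``r = L tan(asin(lambda / 2d)) / pixel_size``.

    Raises
    ------
    ResolutionUnreachableError
        If ``lambda / 2d`` falls outside (0, 1] — the resolution is finer
        than the wavelength permits at any angle.
    """
    s = geom.wavelength / (2.0 * float(d))
    if not 0.0 < s <= 1.0:
        raise ResolutionUnreachableError(
            f"resolution {d} A unreachable at wavelength {geom.wavelength:.4f} A")
    alpha = np.arcsin(s)
    return float(geom.distance * np.tan(alpha) / (geom.pixel_size * 1e-3))


def radius_to_resolution(r_px: float, geom: DetectorGeometry) -> float:
    """Half-period resolution (Angstrom) at a given pixel radius.

    Returns +inf at r = 0 (forward beam).
    """
    r_mm = float(r_px) * geom.pixel_size * 1e-3
    alpha = np.arctan2(r_mm, geom.distance)
    with np.errstate(divide="ignore"):
        return float(geom.wavelength / (2.0 * np.sin(alpha)))
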