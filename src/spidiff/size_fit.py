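"""Sphere-model size fitting on photon frames.

A homogeneous sphere scatters radially symmetrically, so a photon frame is
first reduced to annular bins (1-pixel width by default).  Sums of
independent Poisson counts are Poisson, so the binned log-likelihood is
exact:

    LL(d, Phi) = sum_b [ k_b ln(Phi t_b(d)) - Phi t_b(d) - ln k_b! ],

where ``k_b`` is the photon sum in bin b and ``t_b(d)`` the unit-fluence
expected sum there.  At fixed diameter the fluence maximiser is analytic,
``Phi*(d) = sum_b k_b / sum_b t_b(d)``, leaving a one-dimensional profile
likelihood in the diameter that is scanned on a coarse grid and refined by
bounded scalar minimisation.  The reported goodness of fit is the Poisson
deviance of the binned fit.

Hits whose fitted diameter falls inside a configured window (and, when a
threshold is given, whose deviance is acceptable) are classified as single
particles; clusters and aggregates fit to larger or poorly matching
effective sizes and fall outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .calibration import PhotonFrame
from .errors import NotClassifiableError, UnfittableFrameError
from .geometry import PixelMap
from .simulator import SphereModel, sphere_expected_photons

__all__ = ["SizeFitResult", "SphereFitter", "fit_sphere", "classify_single_particle"]


@dataclass
class SizeFitResult:
    diameter: float        #: nm
    fluence: float         #: photons / um^2
    deviance: float        #: Poisson deviance of the binned fit
    converged: bool        #: False when the optimum sits on the search boundary
    log_likelihood: float
    is_single_particle: bool | None = None


def _poisson_deviance(k: np.ndarray, mu: np.ndarray) -> float:
    """2 sum [k ln(k/mu) - (k - mu)], with k ln k -> 0 at k = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(k > 0, k * np.log(np.where(k > 0, k, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(term - (k - mu)))


class SphereFitter:
    """Radially binned sphere fits against a fixed geometry and mask.

    Caches the per-bin pixel assignment and the unit-fluence templates for
    the coarse diameter grid, so fitting many frames from one run is cheap.

    Parameters
    ----------
    pmap
        Pixel map built from the nominal geometry.
    mask
        True = exclude pixel (detector gaps, beamstop, bad pixels).
    diameter_grid
        Coarse search grid in nm (default 40-120 nm in 0.5 nm steps).
    bin_width
        Radial bin width in pixels.
    density, electrons_per_dalton
        Sphere-material parameters forwarded to the model.
    """

    def __init__(self, pmap: PixelMap, mask: np.ndarray | None = None,
                 diameter_grid: np.ndarray | None = None, bin_width: float = 1.0,
                 density: float = 1.381, electrons_per_dalton: float = 0.53):
        self.pmap = pmap
        self.mask = np.zeros(pmap.q.shape, bool) if mask is None \
            else np.asarray(mask, bool)
        self.use = ~self.mask
        if diameter_grid is None:
            diameter_grid = np.arange(40.0, 120.0 + 1e-9, 0.5)
        self.diameter_grid = np.asarray(diameter_grid, dtype=float)
        self.density = density
        self.epd = electrons_per_dalton

        self.bin_width = float(bin_width)
        r = pmap.r_px[self.use]
        self.bin_index = np.floor(r / bin_width).astype(int)
        self.n_bins = int(self.bin_index.max()) + 1 if self.bin_index.size else 0
        self.bin_npix = np.bincount(self.bin_index, minlength=self.n_bins)
        # unit-fluence binned templates, one row per grid diameter
        self.templates = np.stack([self._template(d) for d in self.diameter_grid])

    def _template(self, diameter: float) -> np.ndarray:
        model = SphereModel(diameter, self.density, self.epd)
        n = sphere_expected_photons(model, 1.0, self.pmap)[self.use]
        return np.bincount(self.bin_index, weights=n, minlength=self.n_bins)

    def _profile_ll(self, k_b: np.ndarray, t_b: np.ndarray) -> tuple[float, float]:
        """Profile log-likelihood over fluence at one diameter."""
        k_tot = k_b.sum()
        t_tot = t_b.sum()
        if k_tot == 0 or t_tot == 0:
            return -np.inf, 0.0
        phi = k_tot / t_tot
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.sum(np.where(k_b > 0, k_b * np.log(phi * t_b), 0.0)) \
                - phi * t_tot - np.sum(gammaln(k_b + 1.0))
        return float(ll), float(phi)

    def fit(self, frame: PhotonFrame | np.ndarray) -> SizeFitResult:
        """Maximum-likelihood (diameter, fluence) for one photon frame."""
        if isinstance(frame, PhotonFrame):
            counts, fmask = frame.counts, frame.mask
        else:
            counts, fmask = np.asarray(frame), None
        use = self.use if fmask is None else self.use & ~fmask
        if fmask is None:
            k_b = np.bincount(self.bin_index, weights=counts[self.use].astype(float),
                              minlength=self.n_bins)
        else:
            r = self.pmap.r_px[use]
            idx = np.floor(r / self.bin_width).astype(int)
            k_b = np.bincount(idx, weights=counts[use].astype(float),
                              minlength=self.n_bins)[: self.n_bins]
        if k_b.sum() == 0:
            raise UnfittableFrameError("no unmasked photons in frame")

        lls = np.array([self._profile_ll(k_b, t)[0] for t in self.templates])
        best = int(np.argmax(lls))

        lo = self.diameter_grid[max(best - 1, 0)]
        hi = self.diameter_grid[min(best + 1, len(self.diameter_grid) - 1)]

        def neg_ll(d: float) -> float:
            return -self._profile_ll(k_b, self._template(d))[0]

        if hi > lo:
            opt = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-3})
            d_hat = float(opt.x)
            ll_hat = -float(opt.fun)
        else:
            d_hat, ll_hat = float(self.diameter_grid[best]), float(lls[best])
        t_hat = self._template(d_hat)
        _, phi_hat = self._profile_ll(k_b, t_hat)
        mu = phi_hat * t_hat
        positive = mu > 0
        deviance = _poisson_deviance(k_b[positive], mu[positive])
        converged = bool(self.diameter_grid[0] < d_hat < self.diameter_grid[-1]
                         and np.isfinite(ll_hat))
        return SizeFitResult(diameter=d_hat, fluence=phi_hat, deviance=deviance,
                             converged=converged, log_likelihood=ll_hat)


def fit_sphere(frame: PhotonFrame | np.ndarray, pmap: PixelMap,
               mask: np.ndarray | None = None,
               diameter_grid: np.ndarray | None = None,
               bin_width: float = 1.0) -> SizeFitResult:
    """One-off sphere fit (constructs a :class:`SphereFitter` per call)."""
    fitter = SphereFitter(pmap, mask=mask, diameter_grid=diameter_grid,
                          bin_width=bin_width)
    return fitter.fit(frame)


def classify_single_particle(result: SizeFitResult,
                             window: tuple[float, float] = (60.0, 85.0),
                             deviance_max: float | None = None) -> bool:
    """True iff the fit converged, the diameter lies in the closed window,
    and (when given) the deviance is below ``deviance_max``.

    Raises
    ------
    NotClassifiableError
        For unconverged fits.
    """
    if not result.converged:
        raise NotClassifiableError("size fit did not converge")
    ok = window[0] <= result.diameter <= window[1]
    if deviance_max is not None:
        ok = ok and result.deviance < deviance_max
    result.is_single_particle = bool(ok)
    return result.is_single_particle
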