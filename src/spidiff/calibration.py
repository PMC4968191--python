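"""ADU-to-photon calibration chain for photon-counting pixel detectors.

The raw readout of each pixel is an analog-to-digital value

    A = pedestal + common_mode + gain * n_photons + read_noise,

so converting to photon counts requires (in order) pedestal subtraction,
per-panel common-mode correction, gain normalisation, and rounding to an
integer count.  The rounding rule is the ceiling threshold

    k = ceil[(A - 0.5 gamma) / gamma],

which places the decision boundary between n and n+1 photons at
(n + 0.5) gamma — the midpoint between the photon peaks of the single-pixel
ADU histogram.  Negative excursions below -0.5 gamma are clamped to zero
photons, since a count cannot be negative.

Gain (gamma, ADU/photon) is estimated per pixel from a low-occupancy
flat-field run by fitting a two-Gaussian mixture to the pixel's ADU
histogram: one peak at zero (read noise) and one at gamma (single photon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    InsufficientDarksError,
    InsufficientStatisticsError,
    InvalidGainError,
    NoBackgroundFramesError,
)

__all__ = [
    "RawFrame",
    "PhotonFrame",
    "CalibrationSet",
    "estimate_pedestal",
    "common_mode_correct",
    "estimate_gain",
    "photonize",
    "average_background",
]


@dataclass
class RawFrame:
    """One detector exposure in ADU, with its panel labelling."""

    data: np.ndarray                 #: 2-D float ADU grid
    panel_id: np.ndarray | None = None  #: integer panel label per pixel
    frame_id: str = ""
    cm_flags: tuple[int, ...] = ()   #: panels where common-mode could not be estimated

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.panel_id is None:
            self.panel_id = np.zeros(self.data.shape, dtype=int)


@dataclass
class PhotonFrame:
    """One detector exposure as non-negative integer photon counts."""

    counts: np.ndarray
    mask: np.ndarray = field(default=None)  #: True = bad/unusable pixel
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.counts[~self.mask] < 0):
            raise ValueError("photon counts must be non-negative on unmasked pixels")


@dataclass
class CalibrationSet:
    """Per-pixel pedestal, read noise, gain and bad-pixel mask."""

    pedestal: np.ndarray
    read_noise: np.ndarray
    gain: np.ndarray
    bad_pixel: np.ndarray

    def __post_init__(self) -> None:
        self.bad_pixel = np.asarray(self.bad_pixel, dtype=bool)
        good = ~self.bad_pixel
        if np.any(~np.isfinite(self.pedestal[good])):
            raise ValueError("pedestal must be finite on unmasked pixels")
        if np.any(self.read_noise[good] < 0):
            raise ValueError("read_noise must be non-negative")
        if np.any(self.gain[good] <= 0):
            raise InvalidGainError("gain must be strictly positive on unmasked pixels")

    @classmethod
    def uniform(cls, shape: tuple[int, int], pedestal: float = 0.0,
                read_noise: float = 0.0, gain: float = 1.0) -> "CalibrationSet":
        """Constant calibration over the whole detector (handy for synthetic data)."""
        return cls(
            pedestal=np.full(shape, float(pedestal)),
            read_noise=np.full(shape, float(read_noise)),
            gain=np.full(shape, float(gain)),
            bad_pixel=np.zeros(shape, dtype=bool),
        )

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("pedestal", data=self.pedestal)
            fh.create_dataset("read_noise", data=self.read_noise)
            fh.create_dataset("gain", data=self.gain)
            fh.create_dataset("mask", data=self.bad_pixel.astype(np.uint8))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "CalibrationSet":
        with h5py.File(path, "r") as fh:
            return cls(
                pedestal=fh["pedestal"][...],
                read_noise=fh["read_noise"][...],
                gain=fh["gain"][...],
                bad_pixel=fh["mask"][...].astype(bool),
            )


def read_mask(path: str | Path, dataset: str = "data/data") -> np.ndarray:
    """Read a standalone bad-pixel mask file (2-D dataset, nonzero = bad)."""
    with h5py.File(path, "r") as fh:
        return fh[dataset][...] != 0


def estimate_pedestal(dark_frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel pedestal (mean) and read noise (sample sd) from a dark stack.

    Parameters
    ----------
    dark_frames
        Stack of shape (n_frames, rows, cols) in ADU; at least two frames.
    """
    darks = np.asarray(dark_frames, dtype=float)
    if darks.ndim != 3 or darks.shape[0] < 2:
        raise InsufficientDarksError("need at least 2 dark frames")
    return darks.mean(axis=0), darks.std(axis=0, ddof=1)


def common_mode_correct(frame: RawFrame, cal: CalibrationSet,
                        signal_cut: float | None = None) -> RawFrame:
    """Subtract the per-panel median of sub-threshold pixels.

    The common mode is a correlated per-panel offset that varies shot to
    shot; it is estimated robustly as the median of unmasked pixels whose
    (pedestal-subtracted) value lies below ``signal_cut``, so that photon
    hits do not bias it.  Panels with no sub-threshold pixels are left
    unchanged and recorded in ``cm_flags``.

    Parameters
    ----------
    signal_cut
        ADU threshold separating "noise" pixels from photon signal.
        Defaults to half the median gain (the single-photon decision
        boundary).
    """
    if signal_cut is None:
        signal_cut = 0.5 * float(np.median(cal.gain[~cal.bad_pixel]))
    data = frame.data.copy()
    flagged: list[int] = []
    for panel in np.unique(frame.panel_id):
        in_panel = frame.panel_id == panel
        noise = in_panel & ~cal.bad_pixel & (data < signal_cut)
        if not noise.any():
            flagged.append(int(panel))
            continue
        data[in_panel] -= np.median(data[noise])
    return RawFrame(data=data, panel_id=frame.panel_id, frame_id=frame.frame_id,
                    cm_flags=tuple(flagged))


def _two_gaussians(x, a0, mu0, s0, a1, mu1, s1):
    return (a0 * np.exp(-0.5 * ((x - mu0) / s0) ** 2)
            + a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2))


def estimate_gain(flatfield_frames: np.ndarray, cal: CalibrationSet,
                  gamma_guess: float = 30.0, min_samples: int = 50,
                  bin_width: float = 1.0) -> np.ndarray:
    """Per-pixel gain from low-occupancy flat-field frames.

    For each pixel, a histogram of pedestal-subtracted ADU values is fit
    with a two-Gaussian mixture; the gain is the separation of the fitted
    means (single-photon peak minus noise peak).  Histogram range is
    [-5 sigma, 2.5 * gamma_guess] at ``bin_width`` ADU per bin.  Fits that
    fail, or whose peak separation is below 3 sigma of the noise peak, are
    returned as NaN (masked).

    Raises
    ------
    InsufficientStatisticsError
        If fewer than ``min_samples`` frames are supplied.
    """
    flats = np.asarray(flatfield_frames, dtype=float)
    if flats.ndim != 3 or flats.shape[0] < min_samples:
        raise InsufficientStatisticsError(
            f"need at least {min_samples} flat-field frames, got "
            f"{0 if flats.ndim != 3 else flats.shape[0]}")
    n_rows, n_cols = flats.shape[1:]
    gain = np.full((n_rows, n_cols), np.nan)
    for i in range(n_rows):
        for j in range(n_cols):
            if cal.bad_pixel[i, j]:
                continue
            sigma = max(float(cal.read_noise[i, j]), 1.0)
            lo, hi = -5.0 * sigma, 2.5 * gamma_guess
            values = flats[:, i, j] - cal.pedestal[i, j]
            hist, edges = np.histogram(values, bins=np.arange(lo, hi + bin_width,
                                                              bin_width))
            centers = 0.5 * (edges[:-1] + edges[1:])
            if hist.sum() == 0:
                continue
            # initial guesses: noise peak at 0, photon peak at the tallest
            # bin beyond the decision threshold
            beyond = centers > 0.5 * gamma_guess
            if not beyond.any() or hist[beyond].sum() == 0:
                continue
            nonzero = np.nonzero(hist)[0]
            if len(nonzero) == 2 and centers[nonzero[1]] > 0.5 * gamma_guess:
                # noiseless limit: two delta peaks — the separation is exact
                # and a Gaussian fit would be degenerate (zero widths)
                gain[i, j] = centers[nonzero[1]] - centers[nonzero[0]]
                continue
            mu1_0 = centers[beyond][np.argmax(hist[beyond])]
            p0 = [max(hist.max(), 1.0), 0.0, sigma,
                  max(hist[beyond].max(), 1.0), mu1_0, sigma]
            try:
                popt, _ = curve_fit(_two_gaussians, centers, hist, p0=p0,
                                    maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            _, mu0, s0, _, mu1, _ = popt
            sep = mu1 - mu0
            if sep < 3.0 * abs(s0) or sep <= 0:
                continue
            gain[i, j] = sep
    return gain


def photonize(adu: np.ndarray, gamma: float | np.ndarray,
              mask: np.ndarray | None = None, frame_id: str = "") -> PhotonFrame:
    """Round a fully corrected ADU grid to integer photon counts.

    Applies ``k = ceil[(A - 0.5 gamma) / gamma]`` with a floor at zero
    photons.  ``gamma`` may be a scalar or a per-pixel gain map.

    Raises
    ------
    InvalidGainError
        If any gain value is non-positive.
    """
    adu = np.asarray(adu, dtype=float)
    gamma_arr = np.broadcast_to(np.asarray(gamma, dtype=float), adu.shape)
    use = np.ones(adu.shape, bool) if mask is None else ~np.asarray(mask, bool)
    if np.any(gamma_arr[use] <= 0):
        raise InvalidGainError("gamma must be strictly positive")
    with np.errstate(invalid="ignore"):
        k = np.ceil((adu - 0.5 * gamma_arr) / gamma_arr)
    k = np.where(use, k, 0)
    k = np.maximum(k, 0).astype(np.int64)
    out_mask = None if mask is None else np.asarray(mask, bool)
    return PhotonFrame(counts=k, mask=out_mask, frame_id=frame_id)


def average_background(frames: np.ndarray, labels) -> np.ndarray:
    """Pixel-wise mean over frames labelled neither hit nor dark.

    Parameters
    ----------
    frames
        Stack (n_frames, rows, cols).
    labels
        Per-frame class labels; any label other than ``"hit"`` / ``"dark"``
        counts as background (blanks).

    Raises
    ------
    NoBackgroundFramesError
        If no frame qualifies.
    """
    frames = np.asarray(frames)
    labels = np.asarray(labels)
    blank = (labels != "hit") & (labels != "dark")
    if not blank.any():
        raise NoBackgroundFramesError("no frames labelled as background")
    return frames[blank].mean(axis=0)
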