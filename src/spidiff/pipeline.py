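"""End-to-end processing of a simulated (or deposited-style) run.

Glue over the core modules: read a raw-ADU CXI file, estimate the pedestal
from the run's dark frames, photonize, find hits, fit sphere sizes and
score the surprise z-statistic against a reference sphere model.  Used by
the command-line interface and by reproducibility checks; every step is
also available individually from the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from . import cxi_io
from .calibration import PhotonFrame, photonize
from .errors import InsufficientDarksError
from .geometry import DetectorGeometry, build_pixel_map
from .profiles import find_hits
from .simulator import ShotConfig, detector_mask, sphere_expected_photons, SphereModel
from .size_fit import SphereFitter, classify_single_particle
from .surprise import minimize_surprise

__all__ = ["RunResults", "process_run"]


@dataclass
class RunResults:
    """Per-frame result table for one processed run."""

    frame_ids: list[str]
    is_hit: np.ndarray
    diameter_nm: np.ndarray        #: NaN for non-hits / unfittable frames
    fluence: np.ndarray
    deviance: np.ndarray
    single_particle: np.ndarray    #: -1 unknown, 0 no, 1 yes
    surprise: np.ndarray
    expected_surprise: np.ndarray
    sigma_surprise: np.ndarray
    zscore: np.ndarray
    best_model_fluence: np.ndarray

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            width = max((len(s) for s in self.frame_ids), default=1)
            fh.create_dataset("frame_id",
                              data=np.array(self.frame_ids, dtype=f"S{width}"))
            for name in ("is_hit", "diameter_nm", "fluence", "deviance",
                         "single_particle", "surprise", "expected_surprise",
                         "sigma_surprise", "zscore", "best_model_fluence"):
                fh.create_dataset(name, data=getattr(self, name))


def process_run(cxi_path: str | Path, geom: DetectorGeometry,
                config: ShotConfig,
                reference_diameter: float = 71.0,
                gamma: float | None = None,
                size_window: tuple[float, float] = (60.0, 85.0),
                fluence_grid: np.ndarray | None = None,
                lit_threshold: int = 1, min_lit_pixels: int = 50,
                surprise_background: float = 1e-3) -> RunResults:
    """Process one raw-ADU run end to end.

    The pedestal is estimated from the run's own dark frames (identified
    as frames with no pixel above the single-photon threshold over the
    nominal pedestal); the gain is taken from ``config`` unless given.
    The surprise is scored against a homogeneous sphere of
    ``reference_diameter`` over ``fluence_grid``.
    """
    gamma = config.gain if gamma is None else gamma
    mask = detector_mask(geom, config)
    pmap = build_pixel_map(geom)

    with cxi_io.read_cxi(cxi_path) as data:
        frames = data[:]
        ids = data.frame_ids or [f"frame-{i:06d}" for i in range(len(frames))]

    # darks: no pixel significantly above the nominal pedestal
    lit = (frames > config.pedestal + 0.5 * gamma).reshape(len(frames), -1)
    is_dark = ~lit.any(axis=1)
    if is_dark.sum() >= 2:
        pedestal = frames[is_dark].mean(axis=0)
    elif np.isfinite(config.pedestal):
        pedestal = np.full(geom.shape, config.pedestal)
    else:
        raise InsufficientDarksError("no dark frames and no configured pedestal")

    photon_frames = [photonize(f - pedestal, gamma, mask=mask, frame_id=i)
                     for f, i in zip(frames, ids)]
    hits = find_hits(photon_frames, lit_threshold=lit_threshold,
                     min_lit_pixels=min_lit_pixels)

    fitter = SphereFitter(pmap, mask=mask)
    ref_base = sphere_expected_photons(SphereModel(reference_diameter), 1.0, pmap)
    if fluence_grid is None:
        fluence_grid = config.fluence_median * np.geomspace(0.25, 4.0, 9)

    n = len(photon_frames)
    out = RunResults(
        frame_ids=list(ids), is_hit=hits,
        diameter_nm=np.full(n, np.nan), fluence=np.full(n, np.nan),
        deviance=np.full(n, np.nan), single_particle=np.full(n, -1, dtype=int),
        surprise=np.full(n, np.nan), expected_surprise=np.full(n, np.nan),
        sigma_surprise=np.full(n, np.nan), zscore=np.full(n, np.nan),
        best_model_fluence=np.full(n, np.nan),
    )
    for i, pf in enumerate(photon_frames):
        if not hits[i]:
            continue
        fit = fitter.fit(pf)
        out.diameter_nm[i] = fit.diameter
        out.fluence[i] = fit.fluence
        out.deviance[i] = fit.deviance
        if fit.converged:
            out.single_particle[i] = int(classify_single_particle(fit, size_window))
        sr = minimize_surprise(pf.counts, [ref_base], fluence_grid, mask=mask,
                               background=surprise_background)
        out.surprise[i] = sr.S
        out.expected_surprise[i] = sr.expected_S
        out.sigma_surprise[i] = sr.sigma_S
        out.zscore[i] = sr.z
        out.best_model_fluence[i] = sr.best_fluence
    return out
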