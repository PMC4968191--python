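"""Synthetic-diffraction generator.

Expected-photon models
----------------------
For a particle of electron count ``N_e`` illuminated by fluence ``Phi``
(photons per square micrometre), the mean photon count in a pixel
subtending solid angle ``dOmega`` at momentum transfer ``q`` is

    n(q) = Phi * r_e^2 * dOmega * |F(q)|^2,

with ``r_e`` the classical electron radius.  Two concrete form factors are
provided:

* a homogeneous sphere of radius R,
  ``F(q) = N_e * 3 (sin u - u cos u) / u^3`` with ``u = q R`` — radially
  symmetric, so the pattern carries size and fluence information only; and
* a shell of twelve spherical blobs at the vertices of a regular
  icosahedron (a coarse stand-in for an icosahedral virus capsid), whose
  coherent sum ``F(q) = f_blob(q) sum_j exp(i q . r_j)`` depends on the
  particle orientation and so exercises orientation search.

Shot simulation
---------------
A run is a mixture of frame classes — single-particle hits, multi-particle
clusters, blanks (beam, no particle), darks (no beam) and flat-fields —
with the shot-to-shot statistics of a SASE free-electron laser: log-normal
fluence jitter and a small Gaussian drift of the beam centre.  Photons are
Poisson-sampled from the expected pattern (attenuated inside a
semi-transparent beamstop), then rendered to detector units as
``ADU = gain * k + pedestal + Gaussian read noise`` with an optional
per-panel common-mode offset, on a four-panel grid with a masked gap
cross.  Every frame carries a ground-truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.spatial.transform import Rotation

from . import cxi_io
from .calibration import RawFrame
from .errors import InvalidOrientationError
from .geometry import DetectorGeometry, PixelMap, build_pixel_map

__all__ = [
    "CLASSICAL_ELECTRON_RADIUS_UM",
    "DALTON_G",
    "SphereModel",
    "IcosaBlobModel",
    "ShotConfig",
    "TruthRecord",
    "sphere_expected_photons",
    "icosa_expected_photons",
    "simulate_shot",
    "simulate_run",
    "read_truth",
]

#: Classical electron radius in micrometres.
CLASSICAL_ELECTRON_RADIUS_UM = 2.8179403262e-9
#: One dalton in grams.
DALTON_G = 1.66053906892e-24


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous sphere, parameterised the way particle sizes are quoted.

    ``electrons_per_dalton`` converts mass to electron count; 0.53 e-/Da is
    the protein-like average.  The absolute intensity scale inherits the
    uncertainty of that composition assumption.
    """

    diameter: float              #: nm
    mass_density: float = 1.381  #: g / cm^3
    electrons_per_dalton: float = 0.53

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.mass_density <= 0:
            raise ValueError("diameter and mass_density must be positive")

    @property
    def radius_angstrom(self) -> float:
        return self.diameter * 10.0 / 2.0

    @property
    def n_electrons(self) -> float:
        radius_cm = self.diameter * 1e-7 / 2.0
        volume_cm3 = 4.0 / 3.0 * np.pi * radius_cm ** 3
        daltons = self.mass_density * volume_cm3 / DALTON_G
        return self.electrons_per_dalton * daltons


def _icosahedron_vertices() -> np.ndarray:
    """Unit-circumradius vertices of a regular icosahedron (12, 3)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a, b in [(1.0, phi)]:
        v += [(0, +a, +b), (0, +a, -b), (0, -a, +b), (0, -a, -b)]
        v += [(+a, +b, 0), (+a, -b, 0), (-a, +b, 0), (-a, -b, 0)]
        v += [(+b, 0, +a), (-b, 0, +a), (+b, 0, -a), (-b, 0, -a)]
    v = np.array(v, dtype=float)
    return v / np.linalg.norm(v[0])


@dataclass(frozen=True)
class IcosaBlobModel:
    """Twelve spherical blobs on the vertices of a regular icosahedron.

    A minimal orientation-dependent particle: the coherent interference of
    the vertex blobs makes the pattern anisotropic while the icosahedral
    point symmetry is preserved exactly.
    """

    blob_radius: float           #: nm
    circum_radius: float         #: nm, centre-to-vertex distance
    n_electrons: float           #: total electron count, split over blobs
    orientation: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.blob_radius <= 0 or self.circum_radius <= 0:
            raise ValueError("radii must be positive")
        qn = np.linalg.norm(self.orientation)
        if not np.isclose(qn, 1.0, atol=1e-8):
            raise InvalidOrientationError(f"quaternion norm {qn} != 1")

    def vertices_angstrom(self, orientation=None) -> np.ndarray:
        """Blob centres (12, 3) in Angstrom, rotated by the quaternion.

        Quaternion convention is (w, x, y, z).
        """
        quat = self.orientation if orientation is None else tuple(orientation)
        qn = np.linalg.norm(quat)
        if not np.isclose(qn, 1.0, atol=1e-8):
            raise InvalidOrientationError(f"quaternion norm {qn} != 1")
        w, x, y, z = quat
        rot = Rotation.from_quat([x, y, z, w])  # scipy is (x, y, z, w)
        return rot.apply(_icosahedron_vertices()) * self.circum_radius * 10.0


def _sphere_form(u: np.ndarray) -> np.ndarray:
    """3 (sin u - u cos u) / u^3, with the u -> 0 limit of 1."""
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    nz = np.abs(u) > 1e-8
    un = u[nz]
    out[nz] = 3.0 * (np.sin(un) - un * np.cos(un)) / un ** 3
    small = ~nz & (u != 0)
    if small.any():
        out[small] = 1.0 - u[small] ** 2 / 10.0
    return out


def _solid_angle(geom: DetectorGeometry) -> float:
    """Per-pixel solid angle in the flat small-angle approximation (sr)."""
    return (geom.pixel_size * 1e-6 / (geom.distance * 1e-3)) ** 2


def sphere_expected_photons(model: SphereModel, fluence: float,
                            pmap: PixelMap) -> np.ndarray:
    """Expected photon count per pixel for a homogeneous sphere.

    ``fluence`` is in photons / um^2; the result is linear in it.
    """
    if fluence < 0:
        raise ValueError("fluence must be non-negative")
    geom = pmap.geometry
    u = pmap.q * model.radius_angstrom
    amp = model.n_electrons * _sphere_form(u)
    return (fluence * CLASSICAL_ELECTRON_RADIUS_UM ** 2 * _solid_angle(geom)
            * amp ** 2)


def _qvec(pmap: PixelMap) -> tuple[np.ndarray, np.ndarray]:
    """In-plane momentum-transfer components (1/A), flat-Ewald approximation."""
    geom = pmap.geometry
    lam = geom.wavelength
    rows = np.arange(geom.n_rows, dtype=float)[:, None]
    cols = np.arange(geom.n_cols, dtype=float)[None, :]
    dy = (rows - geom.beam_center[0]) * geom.pixel_size * 1e-3
    dx = (cols - geom.beam_center[1]) * geom.pixel_size * 1e-3
    scale = 2.0 * np.pi / (lam * geom.distance)
    return scale * np.broadcast_to(dy, (geom.n_rows, geom.n_cols)), \
        scale * np.broadcast_to(dx, (geom.n_rows, geom.n_cols))


def icosa_expected_photons(model: IcosaBlobModel, fluence: float,
                           orientation, pmap: PixelMap) -> np.ndarray:
    """Expected photons for the icosahedral blob shell at one orientation.

    Coherent sum over the twelve blobs on the flat-Ewald approximation
    (q_z neglected; valid at the small scattering angles in scope).
    """
    if fluence < 0:
        raise ValueError("fluence must be non-negative")
    verts = model.vertices_angstrom(orientation)
    qy, qx = _qvec(pmap)
    qmag = np.hypot(qy, qx)
    f_blob = (model.n_electrons / 12.0) * _sphere_form(qmag * model.blob_radius * 10.0)
    phase = qy[..., None] * verts[:, 0] + qx[..., None] * verts[:, 1]
    struct = np.exp(1j * phase).sum(axis=-1)
    amp2 = (f_blob ** 2) * np.abs(struct) ** 2
    return fluence * CLASSICAL_ELECTRON_RADIUS_UM ** 2 * _solid_angle(pmap.geometry) * amp2


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation via a normalised 4-D Gaussian, (w, x, y, z)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


@dataclass(frozen=True)
class ShotConfig:
    """Study conditions for a simulated run.

    Defaults describe a focused hard-X-ray single-particle experiment on
    ~70 nm particles: median fluence 5e11 photons/um^2 with 30 % (in log)
    shot-to-shot jitter, half-pixel beam-pointing drift, a 10 % hit rate
    with occasional multi-particle clusters, interleaved darks and
    flat-fields, a faint uniform background, a semi-transparent beamstop,
    and an ADU rendering chain at 33 ADU/photon.
    """

    fluence_median: float = 5e11      #: photons / um^2 (median of log-normal)
    fluence_sigma: float = 0.3        #: sd of ln(fluence)
    center_drift_px: float = 0.5      #: Gaussian sd of beam-centre drift, per axis
    hit_fraction: float = 0.10
    cluster_fraction: float = 0.02
    dark_fraction: float = 0.05
    flatfield_fraction: float = 0.02
    cluster_size_range: tuple[int, int] = (2, 4)
    flatfield_rate: float = 0.2       #: photons / pixel on flat-field frames
    background_rate: float = 1e-3     #: photons / pixel on beam-on frames
    beamstop_radius_px: float = 20.0
    beamstop_transmission: float = 0.01
    pedestal: float = 20.0            #: ADU
    read_noise: float = 3.0           #: ADU
    gain: float = 33.0                #: ADU / photon
    common_mode_range: float = 0.0    #: per-panel uniform(+-range) ADU offset
    n_panel_blocks: int = 2           #: panels per axis (2 -> 2x2 grid)
    gap_px: int = 2                   #: masked gap width between panels
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hit_fraction", "cluster_fraction", "dark_fraction",
                     "flatfield_fraction", "beamstop_transmission"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = (self.hit_fraction + self.cluster_fraction + self.dark_fraction
                 + self.flatfield_fraction)
        if total > 1.0 + 1e-12:
            raise ValueError("class fractions sum above 1")
        for name in ("fluence_median", "fluence_sigma", "center_drift_px",
                     "flatfield_rate", "background_rate", "beamstop_radius_px",
                     "read_noise", "common_mode_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one simulated frame."""

    frame_class: str                       #: hit / cluster / blank / dark / flatfield
    fluence: float
    diameter: float                        #: nm (0 for beam-off / blank frames)
    orientation: np.ndarray                #: quaternion (w, x, y, z)
    beam_center: tuple[float, float]       #: true per-shot centre (row, col)
    photons: np.ndarray                    #: true Poisson counts before masking
    frame_id: str = ""


def panel_labels(geom: DetectorGeometry, n_blocks: int = 2) -> np.ndarray:
    """Rectangular panel labels: an n_blocks x n_blocks block grid."""
    rows = np.minimum(np.arange(geom.n_rows) * n_blocks // geom.n_rows, n_blocks - 1)
    cols = np.minimum(np.arange(geom.n_cols) * n_blocks // geom.n_cols, n_blocks - 1)
    return rows[:, None] * n_blocks + cols[None, :]


def detector_mask(geom: DetectorGeometry, config: ShotConfig) -> np.ndarray:
    """Static bad-pixel mask: panel-gap cross plus the beamstop disc (True = bad)."""
    mask = np.zeros(geom.shape, dtype=bool)
    nb = config.n_panel_blocks
    for b in range(1, nb):
        r = geom.n_rows * b // nb
        c = geom.n_cols * b // nb
        half = config.gap_px // 2
        mask[max(r - half, 0): r - half + config.gap_px, :] = True
        mask[:, max(c - half, 0): c - half + config.gap_px] = True
    rows = np.arange(geom.n_rows)[:, None] - geom.beam_center[0]
    cols = np.arange(geom.n_cols)[None, :] - geom.beam_center[1]
    mask |= np.hypot(rows, cols) <= config.beamstop_radius_px
    return mask


def _cluster_expected(model: SphereModel, fluence: float, pmap: PixelMap,
                      n_particles: int, rng: np.random.Generator) -> np.ndarray:
    """Coherent sum of touching spheres along random directions."""
    u = pmap.q * model.radius_angstrom
    f1 = model.n_electrons * _sphere_form(u)
    qy, qx = _qvec(pmap)
    positions = [np.zeros(3)]
    for _ in range(n_particles - 1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        base = positions[rng.integers(len(positions))]
        positions.append(base + direction * 2.0 * model.radius_angstrom)
    struct = np.zeros(pmap.q.shape, dtype=complex)
    for p in positions:
        struct += np.exp(1j * (qy * p[0] + qx * p[1]))
    amp2 = f1 ** 2 * np.abs(struct) ** 2
    return (fluence * CLASSICAL_ELECTRON_RADIUS_UM ** 2
            * _solid_angle(pmap.geometry) * amp2)


def simulate_shot(config: ShotConfig, model: SphereModel | IcosaBlobModel,
                  geom: DetectorGeometry, rng: np.random.Generator,
                  frame_class: str | None = None,
                  frame_id: str = "") -> tuple[RawFrame, TruthRecord]:
    """Draw one frame: class, fluence, centre, orientation, photons, ADU.

    ``frame_class`` forces a class instead of sampling the mixture.
    """
    if frame_class is None:
        p = [config.hit_fraction, config.cluster_fraction, config.dark_fraction,
             config.flatfield_fraction]
        p.append(max(1.0 - sum(p), 0.0))
        frame_class = rng.choice(
            ["hit", "cluster", "dark", "flatfield", "blank"], p=np.array(p) / sum(p))

    fluence = config.fluence_median * np.exp(config.fluence_sigma * rng.normal())
    drift = rng.normal(0.0, config.center_drift_px, size=2) \
        if config.center_drift_px > 0 else np.zeros(2)
    center = (geom.beam_center[0] + drift[0], geom.beam_center[1] + drift[1])
    orientation = random_quaternion(rng)

    shot_geom = replace(geom, beam_center=center)
    expected = np.zeros(geom.shape, dtype=float)
    diameter = 0.0
    if frame_class in ("hit", "cluster"):
        pmap = build_pixel_map(shot_geom)
        if isinstance(model, IcosaBlobModel):
            diameter = 2.0 * (model.circum_radius + model.blob_radius)
            expected = icosa_expected_photons(model, fluence, orientation, pmap)
        elif frame_class == "cluster":
            n_part = int(rng.integers(config.cluster_size_range[0],
                                      config.cluster_size_range[1] + 1))
            diameter = model.diameter
            expected = _cluster_expected(model, fluence, pmap, n_part, rng)
        else:
            diameter = model.diameter
            expected = sphere_expected_photons(model, fluence, pmap)
    if frame_class == "flatfield":
        expected = expected + config.flatfield_rate
    elif frame_class != "dark":
        expected = expected + config.background_rate

    # semi-transparent beamstop attenuates the expected signal; the static
    # mask later hides the same region from analysis
    rows = np.arange(geom.n_rows)[:, None] - geom.beam_center[0]
    cols = np.arange(geom.n_cols)[None, :] - geom.beam_center[1]
    in_stop = np.hypot(rows, cols) <= config.beamstop_radius_px
    expected = np.where(in_stop, expected * config.beamstop_transmission, expected)

    photons = rng.poisson(expected)
    adu = photons * config.gain + config.pedestal
    if config.read_noise > 0:
        adu = adu + rng.normal(0.0, config.read_noise, size=geom.shape)
    panels = panel_labels(geom, config.n_panel_blocks)
    if config.common_mode_range > 0:
        offsets = rng.uniform(-config.common_mode_range, config.common_mode_range,
                              size=config.n_panel_blocks ** 2)
        adu = adu + offsets[panels]

    raw = RawFrame(data=adu.astype(float), panel_id=panels, frame_id=frame_id)
    truth = TruthRecord(frame_class=frame_class, fluence=float(fluence),
                        diameter=float(diameter), orientation=orientation,
                        beam_center=center, photons=photons, frame_id=frame_id)
    return raw, truth


def _frame_rng(seed: int, index: int) -> np.random.Generator:
    """Per-frame substream keyed by (seed, index): order-independent."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_run(config: ShotConfig, model, geom: DetectorGeometry,
                 n_frames: int, cxi_path: str | Path,
                 truth_path: str | Path | None = None) -> list[TruthRecord]:
    """Simulate ``n_frames`` shots and write a CXI file plus a truth table.

    Deterministic for a fixed ``config.seed``: each frame uses an
    independent substream keyed by (seed, frame index).
    """
    frames = np.empty((n_frames, *geom.shape), dtype=np.float64)
    truths: list[TruthRecord] = []
    ids = [f"r{config.seed:04d}-f{i:06d}" for i in range(n_frames)]
    for i in range(n_frames):
        raw, truth = simulate_shot(config, model, geom, _frame_rng(config.seed, i),
                                   frame_id=ids[i])
        frames[i] = raw.data
        truths.append(truth)
    cxi_io.write_cxi(frames, cxi_path, geometry=geom, frame_ids=ids)
    if truth_path is not None:
        write_truth(truths, truth_path)
    return truths


def write_truth(truths: list[TruthRecord], path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        classes = [t.frame_class for t in truths]
        width = max((len(s) for s in classes), default=1)
        fh.create_dataset("frame_class", data=np.array(classes, dtype=f"S{width}"))
        fh.create_dataset("fluence", data=np.array([t.fluence for t in truths]))
        fh.create_dataset("diameter_nm", data=np.array([t.diameter for t in truths]))
        fh.create_dataset("orientation",
                          data=np.array([t.orientation for t in truths])
                          if truths else np.zeros((0, 4)))
        fh.create_dataset("beam_center",
                          data=np.array([t.beam_center for t in truths])
                          if truths else np.zeros((0, 2)))
        fh.create_dataset("photons",
                          data=np.array([t.photons for t in truths], dtype=np.int64)
                          if truths else np.zeros((0,), dtype=np.int64))
        idw = max((len(t.frame_id) for t in truths), default=1)
        fh.create_dataset("frame_id",
                          data=np.array([t.frame_id for t in truths],
                                        dtype=f"S{max(idw, 1)}"))


def read_truth(path: str | Path) -> dict:
    with h5py.File(path, "r") as fh:
        return {
            "frame_class": [s.decode() for s in fh["frame_class"][...]],
            "fluence": fh["fluence"][...],
            "diameter_nm": fh["diameter_nm"][...],
            "orientation": fh["orientation"][...],
            "beam_center": fh["beam_center"][...],
            "photons": fh["photons"][...],
            "frame_id": [s.decode() for s in fh["frame_id"][...]],
        }
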