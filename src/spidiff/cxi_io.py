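"""Reading and writing diffraction data in the CXI-flavoured HDF5 layout.

The CXI convention stores a run as one HDF5 file with the frame stack at
``/entry_1/instrument_1/detector_1/data`` (chunked by frame), detector
metadata next to it in SI units, the source energy under
``/entry_1/instrument_1/source_1/energy`` (joules), and per-frame
identifiers at ``/entry_1/experiment_identifier``.  Frame selections
(e.g. curated hit lists) travel as a standalone HDF5 file holding a single
1-D dataset of frame identifiers; bad-pixel masks as a standalone file with
a 2-D dataset where nonzero means bad.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .errors import InvalidDatasetError, MalformedCxiError, MalformedSelectionError
from .geometry import DetectorGeometry

__all__ = [
    "CxiDataset",
    "write_cxi",
    "read_cxi",
    "write_selection",
    "read_selection",
    "validate_selection",
]

#: 1 keV in joules.
KEV_IN_JOULES = 1.602176634e-16

_DATA = "entry_1/instrument_1/detector_1/data"
_DISTANCE = "entry_1/instrument_1/detector_1/distance"
_XPIX = "entry_1/instrument_1/detector_1/x_pixel_size"
_YPIX = "entry_1/instrument_1/detector_1/y_pixel_size"
_ENERGY = "entry_1/instrument_1/source_1/energy"
_IDS = "entry_1/experiment_identifier"
_GEOM = "entry_1/instrument_1/detector_1/geometry_yaml"


def write_cxi(frames, path: str | Path, geometry: DetectorGeometry | None = None,
              frame_ids=None, detector: str = "detector_1") -> None:
    """Write a frame stack and metadata to a CXI file.

    Parameters
    ----------
    frames
        Array-like of shape (n_frames, rows, cols).  Integer input is
        stored as integer photon data, floating input as ADU.
    geometry
        Echoed into the file: distance and pixel size in metres, photon
        energy in joules, plus a YAML dump of the full config for exact
        round-tripping.
    frame_ids
        Per-frame identifier strings; defaults to ``frame-%06d``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise InvalidDatasetError(f"frame stack must be 3-D, got shape {frames.shape}")
    n = frames.shape[0]
    if frame_ids is None:
        frame_ids = [f"frame-{i:06d}" for i in range(n)]
    frame_ids = [str(s) for s in frame_ids]
    if len(frame_ids) != n:
        raise InvalidDatasetError("frame_ids length does not match frame count")

    data_path = _DATA.replace("detector_1", detector)
    with h5py.File(path, "w") as fh:
        chunks = (1, *frames.shape[1:]) if n else None
        fh.create_dataset(data_path, data=frames, chunks=chunks)
        width = max((len(s) for s in frame_ids), default=1)
        fh.create_dataset(_IDS, data=np.array(frame_ids, dtype=f"S{width}"))
        if geometry is not None:
            import yaml

            det = data_path.rsplit("/", 1)[0]
            fh[f"{det}/distance"] = geometry.distance * 1e-3
            fh[f"{det}/x_pixel_size"] = geometry.pixel_size * 1e-6
            fh[f"{det}/y_pixel_size"] = geometry.pixel_size * 1e-6
            fh[_ENERGY] = geometry.photon_energy * KEV_IN_JOULES
            fh[f"{det}/geometry_yaml"] = yaml.safe_dump(geometry.to_dict())


@dataclass
class CxiDataset:
    """Lazy view of one detector's frame stack in an open CXI file.

    Use as a context manager, or call :meth:`close` when done.  Optional
    metadata fields are ``None`` when absent from the file — never
    silently defaulted.
    """

    path: Path
    detector: str = "detector_1"

    def __post_init__(self) -> None:
        self._fh = h5py.File(self.path, "r")
        data_path = _DATA.replace("detector_1", self.detector)
        if "entry_1" not in self._fh or data_path not in self._fh:
            self._fh.close()
            raise MalformedCxiError(f"{self.path}: missing /{data_path}")
        self._data = self._fh[data_path]

    # -- stack access ------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self._data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self._data.shape[1:])

    @property
    def dtype(self):
        return self._data.dtype

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i) -> np.ndarray:
        return self._data[i]

    def __iter__(self):
        for i in range(self.n_frames):
            yield self._data[i]

    # -- metadata ----------------------------------------------------------

    def _scalar(self, path: str):
        path = path.replace("detector_1", self.detector)
        return float(self._fh[path][()]) if path in self._fh else None

    @property
    def distance_mm(self) -> float | None:
        v = self._scalar(_DISTANCE)
        return None if v is None else v * 1e3

    @property
    def pixel_size_um(self) -> float | None:
        v = self._scalar(_XPIX)
        return None if v is None else v * 1e6

    @property
    def photon_energy_kev(self) -> float | None:
        v = self._scalar(_ENERGY)
        return None if v is None else v / KEV_IN_JOULES

    @property
    def frame_ids(self) -> list[str] | None:
        if _IDS not in self._fh:
            return None
        return [s.decode() for s in self._fh[_IDS][...]]

    @property
    def geometry(self) -> DetectorGeometry | None:
        path = _GEOM.replace("detector_1", self.detector)
        if path not in self._fh:
            return None
        import yaml

        raw = self._fh[path][()]
        if isinstance(raw, bytes):
            raw = raw.decode()
        return DetectorGeometry.from_dict(yaml.safe_load(raw))

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "CxiDataset":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_cxi(path: str | Path, detector: str = "detector_1") -> CxiDataset:
    """Open a CXI file for lazy per-frame access."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return CxiDataset(Path(path), detector=detector)


def write_selection(ids, path: str | Path) -> None:
    """Write a hit selection: one 1-D dataset of frame-identifier strings."""
    ids = [str(s) for s in ids]
    width = max((len(s) for s in ids), default=1)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("timestamps", data=np.array(ids, dtype=f"S{width}"))


def read_selection(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as fh:
        if "timestamps" not in fh:
            raise MalformedSelectionError(f"{path}: missing /timestamps dataset")
        return [s.decode() for s in fh["timestamps"][...]]


def validate_selection(selection_ids, cxi: CxiDataset) -> list[str]:
    """Return selection ids absent from the CXI file (orphans).

    Comparison is lexical on the identifier strings.
    """
    have = set(cxi.frame_ids or [])
    return [s for s in selection_ids if s not in have]
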