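"""Core data model and file I/O for FTIR hypercubes, MSI datasets and class maps.

The in-memory containers mirror what the two instruments produce: an FTIR
microscope yields an absorbance spectrum per pixel on a coarse grid (a
hyperspectral cube), while a MALDI mass spectrometry imaging (MSI) run yields a
centroided peak list per pixel on a finer raster.  Both carry physical grid
metadata (pixel pitch in micrometres, origin of pixel (0,0)) so that the two
modalities can be co-registered later.

Conventions
-----------
* Pixel indices are 0-based ``(row, col)``; physical positions refer to pixel
  centres; the origin is the centre of pixel (0,0); x grows rightward with
  columns, y grows downward with rows.
* imzML uses 1-based ``(x, y)`` coordinates; I/O translates so that package
  pixel ``(x_index=0, y_index=0)`` corresponds to imzML ``(1, 1)``.
* FTIR intensities are stored as absorbance.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralAxis",
    "HyperspectralImage",
    "TissueClass",
    "TISSUE_CLASSES",
    "CLASS_IDS",
    "CLASS_COLORS",
    "LabeledSpectrum",
    "ReferenceCollection",
    "TissueClassMap",
    "MsiDataset",
    "MsiPixel",
    "RegionOfInterest",
    "read_hypercube",
    "write_hypercube",
    "read_imzml",
    "write_imzml",
    "FormatError",
    "ValidationError",
]


class FormatError(RuntimeError):
    """A file does not follow the documented container layout."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


# ---------------------------------------------------------------------------
# Spectral axis and hypercube
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered wavenumber axis in cm^-1 with its nominal spectral resolution.

    The default instrument axis spans 900-3600 cm^-1 at a nominal resolution
    of 8 cm^-1, stored at 4 cm^-1 spacing (zero-filling factor 2).
    """

    wavenumbers: np.ndarray
    resolution_cm1: float = 8.0

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        if wn.ndim != 1 or wn.size < 2:
            raise ValidationError("spectral axis needs at least two wavenumbers")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("spectral axis must be strictly monotone")

    @classmethod
    def default(cls, lo: float = 900.0, hi: float = 3600.0,
                spacing: float = 4.0, resolution_cm1: float = 8.0) -> "SpectralAxis":
        n = int(round((hi - lo) / spacing)) + 1
        return cls(np.linspace(lo, hi, n), resolution_cm1=resolution_cm1)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return (self.resolution_cm1 == other.resolution_cm1
                and len(self) == len(other)
                and bool(np.allclose(self.wavenumbers, other.wavenumbers)))

    @property
    def lo(self) -> float:
        return float(self.wavenumbers.min())

    @property
    def hi(self) -> float:
        return float(self.wavenumbers.max())


@dataclass
class HyperspectralImage:
    """FTIR absorbance cube: (rows, cols, n_wavenumbers) on a physical grid."""

    data: np.ndarray
    axis: SpectralAxis
    pixel_size_um: float = 11.05
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("cube must be 3-D (rows, cols, n_wavenumbers)")
        rows, cols, nwn = self.data.shape
        if rows < 1 or cols < 1:
            raise ValidationError("cube must contain at least one pixel")
        if nwn != len(self.axis):
            raise ValidationError(
                f"cube has {nwn} channels but axis has {len(self.axis)}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("cube contains non-finite values")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        self.origin_um = (float(self.origin_um[0]), float(self.origin_um[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    def spectra(self) -> np.ndarray:
        """Pixels flattened row-major into an (n_pixels, n_wavenumbers) array."""
        return self.data.reshape(-1, self.data.shape[2])


# ---------------------------------------------------------------------------
# Tissue classes and labelled references
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueClass:
    id: int
    name: str
    color: tuple[float, float, float]


#: The four-class convention: background (blue), body wall (red),
#: digestive system (green), other tissue (orange).
TISSUE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass(1, "background", (0.0, 0.0, 1.0)),
    TissueClass(2, "body wall", (1.0, 0.0, 0.0)),
    TissueClass(3, "digestive system", (0.0, 0.8, 0.0)),
    TissueClass(4, "other tissue", (1.0, 0.65, 0.0)),
)

CLASS_IDS: tuple[int, ...] = tuple(c.id for c in TISSUE_CLASSES)
CLASS_COLORS: dict[int, tuple[float, float, float]] = {c.id: c.color for c in TISSUE_CLASSES}
CLASS_NAMES: dict[int, str] = {c.id: c.name for c in TISSUE_CLASSES}


@dataclass
class LabeledSpectrum:
    """One reference spectrum with its tissue-class label and provenance."""

    spectrum: np.ndarray
    label: int
    section_id: str
    pixel: tuple[int, int]

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.label not in CLASS_IDS:
            raise ValidationError(f"label must be one of {CLASS_IDS}, got {self.label}")


@dataclass
class ReferenceCollection:
    """Labelled spectra used to train and validate the classifier."""

    items: list[LabeledSpectrum]
    axis: SpectralAxis

    def __post_init__(self) -> None:
        n = len(self.axis)
        for it in self.items:
            if it.spectrum.size != n:
                raise ValidationError("all reference spectra must share the axis")

    def __len__(self) -> int:
        return len(self.items)

    def spectra(self) -> np.ndarray:
        if not self.items:
            return np.empty((0, len(self.axis)))
        return np.stack([it.spectrum for it in self.items])

    def labels(self) -> np.ndarray:
        return np.array([it.label for it in self.items], dtype=int)

    def counts(self) -> dict[tuple[str, int], int]:
        """Number of spectra per (section_id, class id)."""
        out: dict[tuple[str, int], int] = {}
        for it in self.items:
            key = (it.section_id, it.label)
            out[key] = out.get(key, 0) + 1
        return out


@dataclass
class TissueClassMap:
    """Per-pixel predicted (or true) tissue class on a physical grid."""

    labels: np.ndarray
    pixel_size_um: float = 11.05
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValidationError("class map must be 2-D")
        bad = ~np.isin(self.labels, CLASS_IDS)
        if bad.any():
            raise ValidationError("class map contains ids outside {1..4}")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        self.origin_um = (float(self.origin_um[0]), float(self.origin_um[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class RegionOfInterest:
    """Boolean pixel mask on a stated physical grid."""

    mask: np.ndarray
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValidationError("ROI must contain at least one pixel")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")


# ---------------------------------------------------------------------------
# MSI dataset
# ---------------------------------------------------------------------------


@dataclass
class MsiPixel:
    """Centroided peak list of one MSI pixel (0-based grid coordinate)."""

    coord: tuple[int, int]  # (x_index, y_index)
    mz_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_values.size != self.intensities.size:
            raise ValidationError("m/z and intensity arrays must match in length")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be nonnegative")
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            raise ValidationError("m/z values must be strictly increasing")


@dataclass
class MsiDataset:
    """Per-pixel centroid peak lists on a regular raster (default 5 um pitch)."""

    pixels: list[MsiPixel]
    pixel_size_um: float = 5.0
    origin_um: tuple[float, float] = (0.0, 0.0)
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        coords = [p.coord for p in self.pixels]
        if len(set(coords)) != len(coords):
            raise ValidationError("MSI pixel coordinates must be unique")
        self.origin_um = (float(self.origin_um[0]), float(self.origin_um[1]))

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def extent(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding grid, i.e. max indices + 1."""
        if not self.pixels:
            raise ValidationError("empty MSI dataset has no extent")
        xs = max(p.coord[0] for p in self.pixels) + 1
        ys = max(p.coord[1] for p in self.pixels) + 1
        return ys, xs


# ---------------------------------------------------------------------------
# Hypercube container I/O (HDF5 layout: cube / wavenumbers + grid attrs)
# ---------------------------------------------------------------------------

_CUBE_DS = "cube"
_AXIS_DS = "wavenumbers"


def write_hypercube(img: HyperspectralImage, path: str | os.PathLike) -> str:
    """Write an FTIR cube to the package's HDF5 container layout.

    Datasets: ``cube`` (rows, cols, n_wn) float64 and ``wavenumbers`` (n_wn)
    float64; root attributes ``pixel_size_um``, ``origin_um`` and
    ``resolution_cm1``.  Parent directories are created as needed.
    """
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset(_CUBE_DS, data=img.data)
        f.create_dataset(_AXIS_DS, data=img.axis.wavenumbers)
        f.attrs["pixel_size_um"] = img.pixel_size_um
        f.attrs["origin_um"] = np.asarray(img.origin_um, dtype=float)
        f.attrs["resolution_cm1"] = img.axis.resolution_cm1
    return path


def read_hypercube(path: str | os.PathLike) -> HyperspectralImage:
    """Read an FTIR cube written by :func:`write_hypercube`."""
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        if _AXIS_DS not in f:
            raise FormatError(f"{path!r} lacks the wavenumber axis dataset")
        if _CUBE_DS not in f:
            raise FormatError(f"{path!r} lacks the cube dataset")
        wn = np.asarray(f[_AXIS_DS])
        cube = np.asarray(f[_CUBE_DS])
        if cube.ndim != 3 or cube.shape[2] != wn.size:
            raise ValidationError(
                f"cube shape {cube.shape} does not match axis length {wn.size}")
        axis = SpectralAxis(wn, resolution_cm1=float(f.attrs.get("resolution_cm1", 8.0)))
        pix = float(f.attrs.get("pixel_size_um", 11.05))
        origin = tuple(np.asarray(f.attrs.get("origin_um", (0.0, 0.0)), dtype=float))
    return HyperspectralImage(cube, axis, pixel_size_um=pix, origin_um=origin)


# ---------------------------------------------------------------------------
# imzML I/O (pyimzml backed; processed mode default, continuous readable)
# ---------------------------------------------------------------------------


def write_imzml(ds: MsiDataset, path: str | os.PathLike) -> str:
    """Write an MSI dataset to an imzML/ibd pair (processed mode).

    Package 0-based ``(x_index, y_index)`` maps to the standard's 1-based
    ``(x, y)`` coordinates.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if not ds.pixels:
        raise ValidationError("cannot write an empty MSI dataset")
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
    with ImzMLWriter(path, mode="processed", polarity=ds.polarity,
                     intensity_dtype=np.float64) as w:
        for p in ds.pixels:
            w.addSpectrum(p.mz_values, p.intensities,
                          (p.coord[0] + 1, p.coord[1] + 1, 1))
    return path


def read_imzml(path: str | os.PathLike,
               pixel_size_um: float = 5.0) -> MsiDataset:
    """Read an imzML/ibd pair into an :class:`MsiDataset`.

    Works for both processed- and continuous-mode files.  Unsorted peak lists
    are sorted with a logged warning.  The imzML standard's 1-based (x, y)
    coordinates become 0-based ``(x_index, y_index)``.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise IOError(f"missing binary data file {ibd!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pyimzml warns on absent optional accessions
        parser = ImzMLParser(path)
    pixels: list[MsiPixel] = []
    try:
        for i, (x, y, _z) in enumerate(parser.coordinates):
            mzs, ints = parser.getspectrum(i)
            mzs = np.asarray(mzs, dtype=float)
            ints = np.asarray(ints, dtype=float)
            if mzs.size > 1 and not np.all(np.diff(mzs) > 0):
                logger.warning("unsorted m/z array at pixel (%d, %d); sorting", x, y)
                order = np.argsort(mzs, kind="stable")
                mzs, ints = mzs[order], ints[order]
            pixels.append(MsiPixel((int(x) - 1, int(y) - 1), mzs, ints))
    finally:
        parser.m.close()
    return MsiDataset(pixels, pixel_size_um=pixel_size_um)
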