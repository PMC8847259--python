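"""Spectral descriptors: scalar features computed from wavenumber windows.

A descriptor reduces a spectrum to one number over a window — a baseline-
corrected peak height, a band integral, or a ratio of two band integrals.
Banks of such descriptors turn a hyperspectral cube or a reference collection
into the feature matrix the random-decision-forest classifier consumes.

The default bank tiles the whole 900-3600 cm^-1 range with sliding
baseline-corrected integrals at two window widths plus peak heights at a
third tiling, sized to exactly ``target_n`` descriptors (default 700).  The
bank is deterministic for a given axis and serialisable to a plain-text file
so that a trained model's features are portable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .hyperdata import (
    HyperspectralImage,
    ReferenceCollection,
    SpectralAxis,
    ValidationError,
)

__all__ = [
    "DescriptorSpec",
    "DescriptorBank",
    "DescriptorMatrix",
    "build_default_bank",
    "compute_descriptors",
    "save_bank",
    "load_bank",
]

_RATIO_EPS = 1e-12
_KINDS = ("peak_height", "integral", "ratio")
_BASELINES = ("none", "linear_endpoints")


@dataclass(frozen=True)
class DescriptorSpec:
    """One scalar feature: kind, window (cm^-1) and baseline handling."""

    kind: str
    window: tuple[float, float]
    reference_window: tuple[float, float] | None = None
    baseline: str = "linear_endpoints"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown descriptor kind {self.kind!r}")
        if self.baseline not in _BASELINES:
            raise ValidationError(f"unknown baseline mode {self.baseline!r}")
        lo, hi = self.window
        if not lo < hi:
            raise ValidationError("window must satisfy lo < hi")
        if self.kind == "ratio" and self.reference_window is None:
            raise ValidationError("ratio descriptors need a reference_window")


@dataclass(frozen=True)
class DescriptorBank:
    """Ordered, stable list of descriptor specs tied to no particular axis."""

    specs: tuple[DescriptorSpec, ...]

    @property
    def n(self) -> int:
        return len(self.specs)

    def subset(self, indices: np.ndarray | list[int]) -> "DescriptorBank":
        """New bank keeping only the given spec positions (order preserved)."""
        return DescriptorBank(tuple(self.specs[int(i)] for i in indices))


@dataclass
class DescriptorMatrix:
    """(n_spectra, n_descriptors) feature matrix plus its bank and labels."""

    values: np.ndarray
    bank: DescriptorBank
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.bank.n:
            raise ValidationError("matrix column count must equal bank size")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("descriptor matrix contains non-finite values")


def build_default_bank(axis: SpectralAxis, target_n: int = 700) -> DescriptorBank:
    """Deterministic default bank of exactly ``target_n`` descriptors.

    Three families tile [axis.lo, axis.hi]: integrals over narrow (32 cm^-1)
    windows, integrals over wide (96 cm^-1) windows, and peak heights over
    narrow windows, all with linear-endpoint baselines.  Family sizes split
    ``target_n`` as evenly as possible; window start positions are spaced
    evenly over the axis range.
    """
    if target_n < 1:
        raise ValidationError("target_n must be at least 1")
    lo, hi = axis.lo, axis.hi
    if target_n == 1:
        return DescriptorBank((DescriptorSpec("integral", (lo, hi)),))
    families = (("integral", 32.0), ("integral", 96.0), ("peak_height", 32.0))
    base, rem = divmod(target_n, len(families))
    specs: list[DescriptorSpec] = []
    for fi, (kind, width) in enumerate(families):
        n_f = base + (1 if fi < rem else 0)
        if n_f == 0:
            continue
        if width >= hi - lo:
            raise ValidationError(
                f"axis range {hi - lo} cm-1 too narrow for {width} cm-1 windows")
        starts = np.linspace(lo, hi - width, n_f)
        for s in starts:
            specs.append(DescriptorSpec(kind, (float(s), float(s + width))))
    return DescriptorBank(tuple(specs))


def _window_slice(wn: np.ndarray, window: tuple[float, float],
                  min_channels: int = 2) -> slice:
    i0 = int(np.searchsorted(wn, window[0], side="left"))
    i1 = int(np.searchsorted(wn, window[1], side="right"))
    if i1 - i0 < min_channels:
        # widen so a baseline / area is computable over the window
        i1 = min(i0 + min_channels, wn.size)
        i0 = max(i1 - min_channels, 0)
    return slice(i0, i1)


def _band_values(spectra: np.ndarray, wn: np.ndarray,
                 window: tuple[float, float], baseline: str,
                 kind: str) -> np.ndarray:
    # a bare peak height needs only one channel; baselines and areas need two
    need = 1 if (kind == "peak_height" and baseline == "none") else 2
    sl = _window_slice(wn, window, min_channels=need)
    seg = spectra[:, sl]
    w = wn[sl]
    if seg.shape[1] == 1:
        return seg[:, 0]
    if baseline == "linear_endpoints":
        t = (w - w[0]) / (w[-1] - w[0])
        base = seg[:, [0]] * (1.0 - t)[None, :] + seg[:, [-1]] * t[None, :]
        seg = seg - base
    if kind == "peak_height":
        return seg.max(axis=1)
    return np.trapezoid(seg, w, axis=1)


def compute_descriptors(
    spectra: ReferenceCollection | HyperspectralImage | np.ndarray,
    bank: DescriptorBank,
    axis: SpectralAxis | None = None,
) -> DescriptorMatrix:
    """Evaluate a bank on a reference collection, an image, or a raw array.

    Rows follow the input order (for an image: pixels row-major).  Peak
    heights are the window maximum above the linear-endpoint baseline;
    integrals are the trapezoidal area above it; ratios divide two integrals
    with a tiny epsilon guard in the denominator.
    """
    labels = None
    if isinstance(spectra, ReferenceCollection):
        mat, ax = spectra.spectra(), spectra.axis
        labels = spectra.labels()
    elif isinstance(spectra, HyperspectralImage):
        mat, ax = spectra.spectra(), spectra.axis
    else:
        mat = np.asarray(spectra, dtype=float)
        if axis is None:
            raise ValidationError("raw spectra need an explicit axis")
        ax = axis
    if mat.ndim != 2 or mat.shape[1] != len(ax):
        raise ValidationError("spectra length does not match the axis")
    wn = ax.wavenumbers
    out = np.empty((mat.shape[0], bank.n))
    for j, spec in enumerate(bank.specs):
        if spec.kind == "ratio":
            num = _band_values(mat, wn, spec.window, spec.baseline, "integral")
            den = _band_values(mat, wn, spec.reference_window, spec.baseline, "integral")
            out[:, j] = num / (den + _RATIO_EPS)
        else:
            out[:, j] = _band_values(mat, wn, spec.window, spec.baseline, spec.kind)
    return DescriptorMatrix(out, bank, labels)


# ---------------------------------------------------------------------------
# Plain-text bank serialisation: one spec per line
# ---------------------------------------------------------------------------


def save_bank(bank: DescriptorBank, path: str | os.PathLike) -> str:
    """Write a bank as tab-separated lines: kind, window, ref window, baseline."""
    path = os.fspath(path)
    with open(path, "w") as f:
        f.write("# histospec descriptor bank v1\n")
        for s in bank.specs:
            ref = ("%r\t%r" % s.reference_window) if s.reference_window else "-\t-"
            f.write(f"{s.kind}\t{s.window[0]!r}\t{s.window[1]!r}\t{ref}\t{s.baseline}\n")
    return path


def load_bank(path: str | os.PathLike) -> DescriptorBank:
    specs: list[DescriptorSpec] = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, lo, hi, rlo, rhi, baseline = line.split("\t")
            ref = None if rlo == "-" else (float(rlo), float(rhi))
            specs.append(DescriptorSpec(kind, (float(lo), float(hi)), ref, baseline))
    if not specs:
        raise ValidationError(f"no descriptor specs found in {path!r}")
    return DescriptorBank(tuple(specs))
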