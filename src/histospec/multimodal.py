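"""FTIR ↔ MSI co-registration, class-derived ROIs and co-localization statistics.

Both instruments image the same physical section, so alignment comes from the
grid metadata alone: a similarity transform (pixel-pitch ratio plus an origin
offset) maps the coarse FTIR class map onto the fine MSI raster.  Class labels
are nominal, so resampling is nearest-neighbour.  Co-localization of an ion
image with a tissue class is quantified by the fraction of total ion intensity
falling inside the class ROI, and by the enrichment of that fraction over the
ROI's area fraction (enrichment 1 = spatially uniform signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hyperdata import (
    CLASS_IDS,
    RegionOfInterest,
    TissueClassMap,
    ValidationError,
)
from .msi import IonImage

__all__ = [
    "GridTransform",
    "OverlayResult",
    "register_class_map",
    "class_roi",
    "overlay_statistics",
]


@dataclass(frozen=True)
class GridTransform:
    """Similarity transform between two pixel grids.

    ``scale`` is the ratio of source to target pixel pitch (e.g. 11.05/5 when
    projecting an FTIR map onto a 5 µm MSI raster); ``offset_um`` is the
    physical (dx, dy) of the target grid origin relative to the source origin.
    """

    scale: float = 1.0
    offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("transform scale must be positive")


@dataclass
class OverlayResult:
    """Per (tissue class, ion image) co-localization statistics."""

    fraction_inside: dict[tuple[int, int], float]  # (class_id, ion_index) -> fraction
    enrichment: dict[tuple[int, int], float]
    area_fraction: dict[int, float]
    ion_targets: list[float]

    def summary(self) -> str:
        lines = [f"{'class':>6}{'ion m/z':>12}{'fraction':>10}{'enrichment':>12}"]
        for (cid, ion), frac in sorted(self.fraction_inside.items()):
            lines.append(f"{cid:>6}{self.ion_targets[ion]:>12.4f}"
                         f"{frac:>10.4f}{self.enrichment[(cid, ion)]:>12.4f}")
        return "\n".join(lines)


def register_class_map(cmap: TissueClassMap, target_pixel_size_um: float,
                       transform: GridTransform | None = None,
                       target_shape: tuple[int, int] | None = None,
                       ) -> TissueClassMap:
    """Nearest-neighbour resample a class map onto a target grid.

    Target pixel centres are mapped into source pixel coordinates through the
    physical transform; each target pixel takes the label of the nearest
    source pixel.  The label set can only shrink, never grow.  Grids that do
    not overlap at all raise an error.
    """
    if target_pixel_size_um <= 0:
        raise ValidationError("target pixel size must be positive")
    tf = transform or GridTransform(scale=cmap.pixel_size_um / target_pixel_size_um)
    rows_s, cols_s = cmap.shape
    if target_shape is None:
        rows_t = int(round(rows_s * cmap.pixel_size_um / target_pixel_size_um))
        cols_t = int(round(cols_s * cmap.pixel_size_um / target_pixel_size_um))
    else:
        rows_t, cols_t = target_shape
    # physical position (um) of target pixel centres relative to the source
    # origin; source pixel centres sit at index * pitch.
    tr = np.arange(rows_t) * target_pixel_size_um + tf.offset_um[1]
    tc = np.arange(cols_t) * target_pixel_size_um + tf.offset_um[0]
    sr = np.round(tr / cmap.pixel_size_um).astype(int)
    sc = np.round(tc / cmap.pixel_size_um).astype(int)
    in_r = (sr >= 0) & (sr < rows_s)
    in_c = (sc >= 0) & (sc < cols_s)
    if not in_r.any() or not in_c.any():
        raise ValidationError("target grid does not overlap the source grid")
    sr_c = np.clip(sr, 0, rows_s - 1)
    sc_c = np.clip(sc, 0, cols_s - 1)
    labels = cmap.labels[np.ix_(sr_c, sc_c)]
    return TissueClassMap(labels, pixel_size_um=target_pixel_size_um,
                          origin_um=(cmap.origin_um[0] + tf.offset_um[0],
                                     cmap.origin_um[1] + tf.offset_um[1]))


def class_roi(cmap: TissueClassMap, class_id: int) -> RegionOfInterest:
    """Boolean ROI of one tissue class on the map's grid."""
    mask = cmap.labels == class_id
    if not mask.any():
        raise ValidationError(f"class {class_id} is absent from the map")
    return RegionOfInterest(mask, cmap.pixel_size_um, cmap.origin_um)


def overlay_statistics(cmap: TissueClassMap, ions: list[IonImage],
                       transform: GridTransform | None = None) -> OverlayResult:
    """Register the class map onto the ion grid and quantify co-localization.

    For every tissue class and ion image: ``fraction_inside`` = share of the
    ion's total intensity inside the class ROI, ``enrichment`` = that
    fraction divided by the class's area fraction.  Over the classes the
    fractions of one ion sum to 1 (the class map partitions the grid).
    """
    if not ions:
        raise ValidationError("need at least one ion image")
    shapes = {im.intensities.shape for im in ions}
    if len(shapes) != 1:
        raise ValidationError("ion images must share one grid")
    shape = shapes.pop()
    pitch = ions[0].pixel_size_um
    reg = register_class_map(cmap, pitch, transform, target_shape=shape)
    n_pix = reg.labels.size
    area = {cid: float(np.count_nonzero(reg.labels == cid)) / n_pix
            for cid in CLASS_IDS}
    frac: dict[tuple[int, int], float] = {}
    enr: dict[tuple[int, int], float] = {}
    for j, im in enumerate(ions):
        total = im.intensities.sum()
        for cid in CLASS_IDS:
            inside = im.intensities[reg.labels == cid].sum()
            f = float(inside / total) if total > 0 else 0.0
            frac[(cid, j)] = f
            enr[(cid, j)] = f / area[cid] if area[cid] > 0 else 0.0
    return OverlayResult(frac, enr, area, [im.target_mz for im in ions])
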