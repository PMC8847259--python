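"""Synthetic tissue phantoms: FTIR cubes and matching MSI datasets with truth.

The phantom emulates a transverse cross-section of an earthworm: an elliptical
body delimited by a body-wall ring (muscle + epidermis, protein-rich), an inner
digestive-tract ellipse (carbohydrate-rich fingerprint bands), the remaining
interior as "other tissue" (lipid-rich, coelomic fluid like), and embedding
medium (CMC) as background.  Each tissue class carries its own infrared band
table; per-pixel spectra are the class bands plus a random linear baseline,
multiplicative gain jitter and additive channel noise.

Band placement follows the regions that discriminate biological tissue in the
mid-IR: the fingerprint region (~900-1450 cm^-1, carbohydrates / nucleic acids
/ lipids), amide I and II (~1500-1700 cm^-1, proteins) and the C-H stretch
region (~2500-3500 cm^-1, mainly lipids).  The band tables are synthetic — they
reproduce the discriminating regions, not any measured spectrum.

A matching MSI phantom places ether-phosphatidylcholine adduct peaks into
anatomical compartments (epidermis rim, digestive system, interstitial tissue)
with a controlled relative mass-error distribution, mimicking the localization
observed by high-resolution MALDI imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hyperdata import (
    CLASS_IDS,
    HyperspectralImage,
    LabeledSpectrum,
    MsiDataset,
    MsiPixel,
    ReferenceCollection,
    SpectralAxis,
    TissueClassMap,
    ValidationError,
)
from .msi import adduct_mz, parse_lipid_shorthand

__all__ = [
    "BandSpec",
    "EllipseGeometry",
    "PhantomConfig",
    "PhantomTruth",
    "LipidSpatialSpec",
    "DEFAULT_CLASS_BANDS",
    "DEFAULT_LIPID_PANEL",
    "generate_ftir_phantom",
    "generate_reference_collection",
    "generate_msi_phantom",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: centre (cm^-1), sigma (cm^-1), amplitude (AU)."""

    center_cm1: float
    width_cm1: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_cm1 <= 0:
            raise ValidationError("band width must be positive")
        if self.amplitude < 0:
            raise ValidationError("band amplitude must be nonnegative")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = (wavenumbers - self.center_cm1) / self.width_cm1
        return self.amplitude * np.exp(-0.5 * d * d)


# Synthetic per-class band tables, anchored to the discriminating regions:
# background = weak broad CMC carbohydrate band; body wall = strong amide I/II
# plus moderate CH2 stretches; digestive = strong fingerprint carbohydrate
# bands plus moderate amide; other tissue = strong ester carbonyl + CH2 lipid
# bands plus weak amide.  Amide bands are deliberately shared between tissue
# classes at different amplitudes so classes overlap realistically.
DEFAULT_CLASS_BANDS: dict[int, tuple[BandSpec, ...]] = {
    1: (
        BandSpec(1060.0, 50.0, 0.15),
        BandSpec(3400.0, 120.0, 0.05),
    ),
    2: (
        BandSpec(1655.0, 25.0, 1.0),
        BandSpec(1545.0, 25.0, 0.7),
        BandSpec(2852.0, 15.0, 0.25),
        BandSpec(2925.0, 18.0, 0.35),
        BandSpec(1080.0, 40.0, 0.15),
    ),
    3: (
        BandSpec(1030.0, 30.0, 0.8),
        BandSpec(1080.0, 30.0, 0.7),
        BandSpec(1655.0, 25.0, 0.5),
        BandSpec(1545.0, 25.0, 0.35),
        BandSpec(2925.0, 18.0, 0.15),
    ),
    4: (
        BandSpec(1740.0, 18.0, 0.8),
        BandSpec(2852.0, 15.0, 0.6),
        BandSpec(2925.0, 18.0, 0.8),
        BandSpec(1655.0, 25.0, 0.3),
        BandSpec(1545.0, 25.0, 0.2),
        BandSpec(1080.0, 40.0, 0.2),
    ),
}


@dataclass(frozen=True)
class EllipseGeometry:
    """Body outline / body-wall / digestive-tract layout in pixel units."""

    center: tuple[float, float] = (31.5, 31.5)  # (row, col)
    body_semi: tuple[float, float] = (28.0, 24.0)  # (semi_row, semi_col)
    wall_thickness_px: float = 4.0
    digestive_center: tuple[float, float] = (34.0, 30.0)
    digestive_semi: tuple[float, float] = (9.0, 7.0)


@dataclass
class PhantomConfig:
    """Everything needed to synthesise one FTIR phantom section."""

    rows: int = 64
    cols: int = 64
    axis: SpectralAxis = field(default_factory=SpectralAxis.default)
    pixel_size_um: float = 11.05
    geometry: EllipseGeometry = field(default_factory=EllipseGeometry)
    class_bands: dict[int, tuple[BandSpec, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_BANDS))
    noise_sd: float = 0.05
    baseline_slope_sd: float = 0.02
    gain_jitter_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("phantom grid must be at least 1x1")
        if min(self.noise_sd, self.baseline_slope_sd, self.gain_jitter_sd) < 0:
            raise ValidationError("noise parameters must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth of a phantom: class map plus anatomical compartment masks."""

    class_map: TissueClassMap
    compartment_masks: dict[str, np.ndarray]
    injected_mass_error_ppm_sd: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class LipidSpatialSpec:
    """Where and how strongly one lipid adduct appears in the MSI phantom."""

    species_name: str
    adduct: str
    compartment: int | str  # TissueClass id or "epidermis_rim" / "interstitial"
    mean_intensity: float = 100.0
    intensity_cv: float = 0.5
    mass_error_ppm_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_intensity <= 0:
            raise ValidationError("mean_intensity must be positive")
        if self.mass_error_ppm_sd < 0:
            raise ValidationError("mass_error_ppm_sd must be nonnegative")


#: Default three-lipid panel: one ether-PC per compartment, mirroring the
#: localization of the potassiated epidermis lipid, the sodiated digestive
#: lipid and the protonated coelomic-fluid/muscle lipid.
DEFAULT_LIPID_PANEL: tuple[LipidSpatialSpec, ...] = (
    LipidSpatialSpec("PC(O-40:1)", "[M+K]+", "epidermis_rim"),
    LipidSpatialSpec("PC(O-36:5)", "[M+Na]+", 3),
    LipidSpatialSpec("PC(O-34:0)", "[M+H]+", "interstitial"),
)


# ---------------------------------------------------------------------------
# FTIR phantom
# ---------------------------------------------------------------------------


def _ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                  semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols]
    return (((rr - center[0]) / semi[0]) ** 2
            + ((cc - center[1]) / semi[1]) ** 2) <= 1.0


def _truth_maps(cfg: PhantomConfig) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    g = cfg.geometry
    body = _ellipse_mask(cfg.rows, cfg.cols, g.center, g.body_semi)
    inner_semi = (g.body_semi[0] - g.wall_thickness_px,
                  g.body_semi[1] - g.wall_thickness_px)
    if min(inner_semi) <= 0:
        raise ValidationError("body-wall ring consumes the whole body (zero-area interior)")
    interior = _ellipse_mask(cfg.rows, cfg.cols, g.center, inner_semi)
    wall = body & ~interior
    if not wall.any():
        raise ValidationError("degenerate geometry: body-wall ring has zero area")
    digestive = _ellipse_mask(cfg.rows, cfg.cols, g.digestive_center, g.digestive_semi)
    if not digestive.any() or (digestive & ~interior).any():
        raise ValidationError("digestive ellipse must lie strictly inside the body wall")
    other = interior & ~digestive
    labels = np.ones((cfg.rows, cfg.cols), dtype=int)  # background
    labels[wall] = 2
    labels[digestive] = 3
    labels[other] = 4
    # epidermis rim: outermost 2-pixel shell of the body wall
    eroded = ndimage.binary_erosion(body, iterations=2, border_value=0)
    rim = wall & ~eroded
    masks = {
        "background": labels == 1,
        "body_wall": wall,
        "digestive": digestive,
        "other_tissue": other,
        "epidermis_rim": rim,
        "interstitial": other.copy(),
    }
    return labels, masks


def generate_ftir_phantom(cfg: PhantomConfig) -> tuple[HyperspectralImage, PhantomTruth]:
    """Synthesise one FTIR section and its ground truth.

    Each pixel's spectrum is ``gain * sum(class bands) + linear baseline +
    N(0, noise_sd)`` per channel; deterministic for a given ``cfg.seed``.
    """
    labels, masks = _truth_maps(cfg)
    rng = np.random.default_rng(cfg.seed)
    wn = cfg.axis.wavenumbers
    nwn = wn.size
    # pure class spectra
    pure = {cid: np.sum([b.profile(wn) for b in cfg.class_bands[cid]], axis=0)
            for cid in CLASS_IDS}
    cube = np.empty((cfg.rows, cfg.cols, nwn))
    for cid in CLASS_IDS:
        cube[labels == cid] = pure[cid]
    npix = cfg.rows * cfg.cols
    gain = 1.0 + cfg.gain_jitter_sd * rng.standard_normal((cfg.rows, cfg.cols))
    slope = cfg.baseline_slope_sd * rng.standard_normal((cfg.rows, cfg.cols))
    ramp = (wn - wn.min()) / (wn.max() - wn.min())
    cube *= gain[..., None]
    cube += slope[..., None] * ramp[None, None, :]
    if cfg.noise_sd > 0:
        cube += cfg.noise_sd * rng.standard_normal(cube.shape)
    img = HyperspectralImage(cube, cfg.axis, pixel_size_um=cfg.pixel_size_um)
    truth = PhantomTruth(
        class_map=TissueClassMap(labels, pixel_size_um=cfg.pixel_size_um),
        compartment_masks=masks,
    )
    return img, truth


# ---------------------------------------------------------------------------
# Reference collection (30 spectra / class / section protocol)
# ---------------------------------------------------------------------------


def generate_reference_collection(
    phantoms: list[tuple[HyperspectralImage, PhantomTruth]],
    per_class: int = 30,
    seed: int = 0,
) -> ReferenceCollection:
    """Sample the labelling protocol: ``per_class`` pixels per class per section.

    Sampling is uniform without replacement within each (section, class)
    stratum; labels come from the ground-truth map.  Five sections at the
    default of 30 per class yield the 600-spectrum collection (120 per
    section).
    """
    if not phantoms:
        raise ValidationError("need at least one phantom section")
    rng = np.random.default_rng(seed)
    axis = phantoms[0][0].axis
    items: list[LabeledSpectrum] = []
    for si, (img, truth) in enumerate(phantoms):
        section_id = f"section-{si + 1}"
        labels = truth.class_map.labels
        for cid in CLASS_IDS:
            rr, cc = np.nonzero(labels == cid)
            if rr.size < per_class:
                raise ValidationError(
                    f"{section_id}: class {cid} has only {rr.size} pixels, "
                    f"need {per_class}")
            if per_class == 0:
                continue
            pick = rng.choice(rr.size, size=per_class, replace=False)
            for k in pick:
                r, c = int(rr[k]), int(cc[k])
                items.append(LabeledSpectrum(img.data[r, c], cid, section_id, (r, c)))
    return ReferenceCollection(items, axis)


# ---------------------------------------------------------------------------
# MSI phantom
# ---------------------------------------------------------------------------

_NOISE_PEAKS_PER_PIXEL = 5
_NOISE_MZ_RANGE = (700.0, 900.0)


def _compartment_mask(truth: PhantomTruth, compartment: int | str) -> np.ndarray:
    if isinstance(compartment, (int, np.integer)):
        return truth.class_map.labels == int(compartment)
    try:
        return truth.compartment_masks[str(compartment)]
    except KeyError:
        raise ValidationError(f"unknown compartment {compartment!r}") from None


def generate_msi_phantom(
    truth: PhantomTruth,
    species: list[LipidSpatialSpec] | tuple[LipidSpatialSpec, ...] = DEFAULT_LIPID_PANEL,
    pixel_size_um: float = 5.0,
    seed: int = 0,
) -> MsiDataset:
    """Synthesise a MALDI-MSI raster matching a phantom's ground truth.

    The MSI grid covers the FTIR truth extent at ``pixel_size_um``.  In pixels
    whose centre falls inside a species' compartment a peak is placed at
    ``theoretical_mz * (1 + eps * 1e-6)`` with ``eps ~ N(0, mass_error_ppm_sd)``
    and a lognormal intensity of the stated mean and coefficient of variation.
    A sparse uniform "chemical noise" peak set (1% of the species mean
    intensity) is added to every pixel.
    """
    if not species:
        raise ValidationError("species list must be non-empty")
    rng = np.random.default_rng(seed)
    ftir_pitch = truth.class_map.pixel_size_um
    rows_f, cols_f = truth.class_map.shape
    height_um = rows_f * ftir_pitch
    width_um = cols_f * ftir_pitch
    n_rows = int(np.ceil(height_um / pixel_size_um))
    n_cols = int(np.ceil(width_um / pixel_size_um))

    # resolve species targets and compartment masks up front
    resolved = []
    for sp in species:
        lipid = parse_lipid_shorthand(sp.species_name)
        mz = adduct_mz(lipid.formula, sp.adduct)
        mask = _compartment_mask(truth, sp.compartment)
        # lognormal parameterised by mean and CV
        sigma2 = np.log(1.0 + sp.intensity_cv ** 2)
        mu = np.log(sp.mean_intensity) - sigma2 / 2.0
        resolved.append((sp, mz, mask, mu, np.sqrt(sigma2)))
        truth.injected_mass_error_ppm_sd[sp.species_name] = sp.mass_error_ppm_sd
    mean_ref = float(np.mean([sp.mean_intensity for sp in species]))

    pixels: list[MsiPixel] = []
    for iy in range(n_rows):
        for ix in range(n_cols):
            # physical centre of this MSI pixel -> containing FTIR pixel
            cy = (iy + 0.5) * pixel_size_um
            cx = (ix + 0.5) * pixel_size_um
            fr = int(cy // ftir_pitch)
            fc = int(cx // ftir_pitch)
            in_grid = fr < rows_f and fc < cols_f
            mzs: list[float] = []
            ints: list[float] = []
            for sp, mz0, mask, mu, sig in resolved:
                if in_grid and mask[fr, fc]:
                    eps = sp.mass_error_ppm_sd * rng.standard_normal()
                    mzs.append(mz0 * (1.0 + eps * 1e-6))
                    ints.append(float(np.exp(mu + sig * rng.standard_normal())))
            noise_mz = rng.uniform(*_NOISE_MZ_RANGE, size=_NOISE_PEAKS_PER_PIXEL)
            noise_int = rng.uniform(0.0, 0.01 * mean_ref, size=_NOISE_PEAKS_PER_PIXEL)
            mz_arr = np.concatenate([np.asarray(mzs), noise_mz])
            int_arr = np.concatenate([np.asarray(ints), noise_int])
            order = np.argsort(mz_arr, kind="stable")
            mz_arr, int_arr = mz_arr[order], int_arr[order]
            # merge exact duplicates (vanishingly rare with uniform noise)
            if mz_arr.size > 1 and np.any(np.diff(mz_arr) <= 0):
                keep = np.concatenate([[True], np.diff(mz_arr) > 0])
                int_arr = np.add.reduceat(int_arr, np.nonzero(keep)[0])
                mz_arr = mz_arr[keep]
            pixels.append(MsiPixel((ix, iy), mz_arr, int_arr))
    return MsiDataset(pixels, pixel_size_um=pixel_size_um)
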