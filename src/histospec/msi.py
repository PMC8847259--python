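"""MALDI-MSI analysis: lipid mass arithmetic, ion images and mass accuracy.

Tentative lipid identification in high-resolution MALDI imaging rests on
accurate precursor mass: a shorthand such as ``PC(O-36:5)`` (an ether-linked
phosphatidylcholine with 36 side-chain carbons and 5 double bonds) determines
an elemental formula, its monoisotopic mass M, and the m/z of its singly
charged cation adducts [M+H]+, [M+Na]+ and [M+K]+ (cation mass added, one
electron mass subtracted).

Ion images are extracted with a relative (ppm) mass tolerance: a pixel's
intensity is the summed intensity of its peaks within ``target * (1 ± tol*1e-6)``.
Mass accuracy across a dataset is the root-mean-square of per-pixel deviations
Δm (in ppm, closest peak) of every pixel containing the targeted ion within a
±4 ppm search window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .hyperdata import MsiDataset, ValidationError

__all__ = [
    "ElementalFormula",
    "LipidSpecies",
    "AdductSpec",
    "ADDUCTS",
    "IonImage",
    "MassAccuracyResult",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "parse_lipid_shorthand",
    "build_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "extract_ion_image",
    "mass_accuracy_rmse",
    "rgb_composite",
    "LipidParseError",
]

#: Monoisotopic atomic masses (u), CODATA/IUPAC values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "Na": 22.98976928,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.00054858


class LipidParseError(ValueError):
    """Shorthand text does not match a supported lipid grammar."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts over the supported element set {C, H, N, O, P, Na, K}."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValidationError(f"unsupported element {el!r}")
            if n < 0:
                raise ValidationError(f"negative count for element {el!r}")
        if not clean:
            raise ValidationError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __str__(self) -> str:
        order = ("C", "H", "N", "O", "P", "Na", "K")
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
                       for el in order if el in self.counts)


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed phosphatidylcholine species."""

    shorthand: str
    headgroup: str
    bond: str  # "diacyl" | "ether"
    carbons: int
    double_bonds: int
    formula: ElementalFormula


#: Supported singly charged positive adducts: name -> cation element.
ADDUCTS: dict[str, str] = {
    "[M+H]+": "H",
    "[M+Na]+": "Na",
    "[M+K]+": "K",
}


@dataclass(frozen=True)
class AdductSpec:
    name: str
    cation_element: str
    charge: int = 1

    @classmethod
    def from_name(cls, name: str) -> "AdductSpec":
        key = name.strip()
        if key not in ADDUCTS:
            raise ValidationError(
                f"unsupported adduct {name!r}; supported: {sorted(ADDUCTS)}")
        return cls(key, ADDUCTS[key])


# PC(36:5) / PC(O-36:5) / PC-O-36:5 / "PC (O-36:5)", case/whitespace tolerant
_SHORTHAND_RE = re.compile(
    r"""^\s*(?P<head>[A-Za-z]+)\s*
        (?:\(\s*(?P<ether1>O-)?\s*(?P<c1>\d+)\s*:\s*(?P<d1>\d+)\s*\)
          |-\s*(?P<ether2>O-)\s*(?P<c2>\d+)\s*:\s*(?P<d2>\d+))
        \s*$""",
    re.VERBOSE | re.IGNORECASE,
)


def parse_lipid_shorthand(text: str) -> LipidSpecies:
    """Parse lipid shorthand like ``PC(O-36:5)`` into a species with formula.

    Supported grammar: ``PC(C:D)`` (diacyl) and ``PC(O-C:D)`` / ``PC-O-C:D``
    (ether-linked), whitespace and case tolerant.  Only the PC headgroup is
    implemented; the headgroup table is the extension point.
    """
    m = _SHORTHAND_RE.match(text)
    if not m:
        raise LipidParseError(f"malformed lipid shorthand {text!r}")
    head = m.group("head").upper()
    if head != "PC":
        raise LipidParseError(f"unsupported headgroup {m.group('head')!r} in {text!r}")
    ether = bool(m.group("ether1") or m.group("ether2"))
    carbons = int(m.group("c1") or m.group("c2"))
    dbonds = int(m.group("d1") or m.group("d2"))
    if carbons < 2:
        raise LipidParseError(f"implausible carbon count {carbons} in {text!r}")
    species = LipidSpecies(
        shorthand=text.strip(),
        headgroup="PC",
        bond="ether" if ether else "diacyl",
        carbons=carbons,
        double_bonds=dbonds,
        formula=None,  # type: ignore[arg-type]
    )
    formula = build_formula(species)
    object.__setattr__(species, "formula", formula)
    return species


def build_formula(species: LipidSpecies) -> ElementalFormula:
    """Elemental formula of a PC species from its shorthand parameters.

    Construction rule (glycerophosphocholine backbone + side chains):
    diacyl ``PC(C:D)`` -> C_{C+8} H_{2C-2D+16} N O8 P; ether ``PC(O-C:D)`` ->
    C_{C+8} H_{2C-2D+18} N O7 P (one ester oxygen replaced by an ether
    linkage, two additional hydrogens).
    """
    c, d = species.carbons, species.double_bonds
    if species.bond == "ether":
        h = 2 * c - 2 * d + 18
        o = 7
    else:
        h = 2 * c - 2 * d + 16
        o = 8
    if h <= 0:
        raise ValidationError(
            f"{species.shorthand}: {d} double bonds exceed what {c} carbons allow")
    return ElementalFormula({"C": c + 8, "H": h, "N": 1, "O": o, "P": 1})


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Neutral monoisotopic mass in u."""
    return float(sum(n * MONOISOTOPIC_MASS[el] for el, n in formula.counts.items()))


def adduct_mz(formula: ElementalFormula, adduct: str | AdductSpec) -> float:
    """m/z of a singly charged positive adduct: M + m(cation) - m(electron)."""
    spec = adduct if isinstance(adduct, AdductSpec) else AdductSpec.from_name(adduct)
    return monoisotopic_mass(formula) + MONOISOTOPIC_MASS[spec.cation_element] - ELECTRON_MASS


# ---------------------------------------------------------------------------
# Ion images and mass accuracy
# ---------------------------------------------------------------------------


@dataclass
class IonImage:
    """Per-pixel summed intensity of one m/z bin on the MSI grid."""

    intensities: np.ndarray
    target_mz: float
    tolerance_ppm: float = 2.5
    pixel_size_um: float = 5.0
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValidationError("ion image intensities must be nonnegative")
        if self.tolerance_ppm <= 0:
            raise ValidationError("tolerance must be positive")


@dataclass
class MassAccuracyResult:
    """RMSE of per-pixel mass deviations of a targeted ion.

    ``defined`` is False when no pixel contains the ion; the RMSE is then
    meaningless and must not be read.
    """

    rmse_ppm: float
    n_spectra: int
    window_ppm: float
    delta_ppm: np.ndarray = field(default_factory=lambda: np.empty(0))
    defined: bool = True


def extract_ion_image(ds: MsiDataset, target_mz: float,
                      tolerance_ppm: float = 2.5) -> IonImage:
    """Extract an ion image with a ±``tolerance_ppm`` bin around ``target_mz``.

    Per pixel, intensity is the sum of peak intensities whose m/z lies in
    ``[target*(1-tol*1e-6), target*(1+tol*1e-6)]`` (inclusive bounds); pixels
    without matching peaks are 0.  The grid shape is the dataset extent.
    """
    if target_mz <= 0:
        raise ValidationError("target m/z must be positive")
    if not ds.pixels:
        raise ValidationError("cannot extract an ion image from an empty dataset")
    rows, cols = ds.extent
    img = np.zeros((rows, cols))
    lo = target_mz * (1.0 - tolerance_ppm * 1e-6)
    hi = target_mz * (1.0 + tolerance_ppm * 1e-6)
    for p in ds.pixels:
        i0 = np.searchsorted(p.mz_values, lo, side="left")
        i1 = np.searchsorted(p.mz_values, hi, side="right")
        if i1 > i0:
            img[p.coord[1], p.coord[0]] = p.intensities[i0:i1].sum()
    return IonImage(img, target_mz, tolerance_ppm, ds.pixel_size_um, ds.origin_um)


def mass_accuracy_rmse(ds: MsiDataset, target_mz: float,
                       window_ppm: float = 4.0) -> MassAccuracyResult:
    """Mass-accuracy RMSE of a targeted ion over all pixels that contain it.

    For each pixel with at least one peak within ±``window_ppm`` of
    ``target_mz``, the deviation is ``(closest peak m/z - target)/target*1e6``;
    the RMSE is the root mean square of these per-pixel deviations.
    """
    if target_mz <= 0:
        raise ValidationError("target m/z must be positive")
    half = target_mz * window_ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    deltas = []
    for p in ds.pixels:
        i0 = np.searchsorted(p.mz_values, lo, side="left")
        i1 = np.searchsorted(p.mz_values, hi, side="right")
        if i1 > i0:
            cand = p.mz_values[i0:i1]
            closest = cand[np.argmin(np.abs(cand - target_mz))]
            deltas.append((closest - target_mz) / target_mz * 1e6)
    if not deltas:
        return MassAccuracyResult(float("nan"), 0, window_ppm, defined=False)
    d = np.asarray(deltas)
    return MassAccuracyResult(float(np.sqrt(np.mean(d * d))), d.size, window_ppm, d)


def rgb_composite(images: list[IonImage] | tuple[IonImage, ...]) -> np.ndarray:
    """Three ion images -> (rows, cols, 3) RGB with per-channel min-max scaling.

    Each channel is normalised to [0, 1] independently; an all-zero channel
    stays zero.
    """
    if len(images) != 3:
        raise ValidationError("rgb_composite needs exactly three ion images")
    shapes = {im.intensities.shape for im in images}
    if len(shapes) != 1:
        raise ValidationError("ion images must share one grid")
    out = np.zeros(images[0].intensities.shape + (3,))
    for ch, im in enumerate(images):
        v = im.intensities
        vmin, vmax = v.min(), v.max()
        if vmax > vmin:
            out[..., ch] = (v - vmin) / (vmax - vmin)
        elif vmax > 0:
            out[..., ch] = 1.0
    return out
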