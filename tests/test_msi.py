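"""Lipid mass arithmetic, ion-image extraction and mass-accuracy RMSE."""

import numpy as np
import pytest

import histospec as hs
from histospec.hyperdata import ValidationError
from histospec.msi import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    ElementalFormula,
    LipidParseError,
    rgb_composite,
)

from conftest import make_msi_dataset


class TestShorthandParsing:
    @pytest.mark.parametrize("text, bond, c, d", [
        ("PC(O-40:1)", "ether", 40, 1),
        ("PC (O-36:5)", "ether", 36, 5),
        ("PC-O-34:0", "ether", 34, 0),
        ("pc(o-34:0)", "ether", 34, 0),
        ("PC(34:0)", "diacyl", 34, 0),
        ("PC( 36 : 2 )", "diacyl", 36, 2),
    ])
    def test_grammar_variants(self, text, bond, c, d):
        sp = hs.parse_lipid_shorthand(text)
        assert (sp.bond, sp.carbons, sp.double_bonds) == (bond, c, d)

    @pytest.mark.parametrize("bad", ["PE(34:1)", "PC(34)", "PC", "34:1", "PC(O-1:0)"])
    def test_malformed_or_unsupported_rejected(self, bad):
        with pytest.raises(LipidParseError):
            hs.parse_lipid_shorthand(bad)


class TestFormulaRule:
    @pytest.mark.parametrize("shorthand, expected", [
        ("PC(O-34:0)", {"C": 42, "H": 86, "N": 1, "O": 7, "P": 1}),
        ("PC(O-36:5)", {"C": 44, "H": 80, "N": 1, "O": 7, "P": 1}),
        ("PC(O-40:1)", {"C": 48, "H": 96, "N": 1, "O": 7, "P": 1}),
    ])
    def test_ether_pc_formulas(self, shorthand, expected):
        assert hs.parse_lipid_shorthand(shorthand).formula.counts == expected

    def test_excessive_double_bonds_rejected(self):
        with pytest.raises(ValidationError):
            hs.parse_lipid_shorthand("PC(4:30)")


class TestMasses:
    def test_water_monoisotopic_mass(self):
        f = ElementalFormula({"H": 2, "O": 1})
        assert hs.monoisotopic_mass(f) == pytest.approx(18.0105646, abs=5e-7)

    def test_empty_formula_rejected(self):
        with pytest.raises(ValidationError):
            ElementalFormula({})

    def test_neutral_pc_o_34_mass(self):
        f = ElementalFormula({"C": 42, "H": 86, "N": 1, "O": 7, "P": 1})
        assert hs.monoisotopic_mass(f) == pytest.approx(747.6142, abs=0.0005)

    @pytest.mark.parametrize("shorthand, adduct, mz", [
        ("PC(O-34:0)", "[M+H]+", 748.6215),
        ("PC(O-36:5)", "[M+Na]+", 788.5565),
        ("PC(O-40:1)", "[M+K]+", 868.6556),
    ])
    def test_adduct_mz_reproduces_reported_values(self, shorthand, adduct, mz):
        f = hs.parse_lipid_shorthand(shorthand).formula
        assert hs.adduct_mz(f, adduct) == pytest.approx(mz, abs=0.001)

    def test_adduct_order_follows_cation_mass(self):
        f = hs.parse_lipid_shorthand("PC(O-36:5)").formula
        h, na, k = (hs.adduct_mz(f, a) for a in ("[M+H]+", "[M+Na]+", "[M+K]+"))
        assert h < na < k

    def test_electron_mass_subtracted(self):
        f = ElementalFormula({"H": 1})
        assert hs.adduct_mz(f, "[M+H]+") == pytest.approx(
            2 * MONOISOTOPIC_MASS["H"] - ELECTRON_MASS, abs=1e-9)

    def test_unsupported_adduct_rejected(self):
        f = ElementalFormula({"C": 1})
        with pytest.raises(ValidationError):
            hs.adduct_mz(f, "[M+NH4]+")


class TestIonImages:
    def test_exact_peak_recovered(self):
        ds = make_msi_dataset({(0, 0): [(788.5565, 5.0)], (1, 0): [(700.0, 9.0)]})
        im = hs.extract_ion_image(ds, 788.5565, 2.5)
        assert im.intensities[0, 0] == 5.0
        assert im.intensities[0, 1] == 0.0

    def test_peak_outside_tolerance_excluded(self):
        target = 788.5565
        ds = make_msi_dataset({(0, 0): [(target * (1 + 3e-6), 5.0)]})
        im = hs.extract_ion_image(ds, target, 2.5)
        assert im.intensities[0, 0] == 0.0

    def test_in_bin_peaks_summed(self):
        target = 800.0
        ds = make_msi_dataset({(0, 0): [(target * (1 - 1e-6), 2.0),
                                        (target * (1 + 1e-6), 3.0)]})
        im = hs.extract_ion_image(ds, target, 2.5)
        assert im.intensities[0, 0] == 5.0

    def test_total_intensity_monotone_in_tolerance(self, msi_phantom):
        totals = [hs.extract_ion_image(msi_phantom, 788.5565, tol).intensities.sum()
                  for tol in (0.5, 1.0, 2.5, 5.0, 10.0)]
        assert all(a <= b for a, b in zip(totals, totals[1:]))

    def test_digestive_lipid_localized(self, phantom1, msi_phantom):
        _, truth = phantom1
        im = hs.extract_ion_image(msi_phantom, 788.5565, 2.5)
        dig = truth.compartment_masks["digestive"]
        pitch_f = truth.class_map.pixel_size_um
        strong = np.argwhere(im.intensities > 10.0)
        assert strong.size > 0
        for r, c in strong:
            cy = (r + 0.5) * msi_phantom.pixel_size_um
            cx = (c + 0.5) * msi_phantom.pixel_size_um
            assert dig[int(cy // pitch_f), int(cx // pitch_f)]

    def test_empty_dataset_rejected(self):
        from histospec.hyperdata import MsiDataset

        with pytest.raises(ValidationError):
            hs.extract_ion_image(MsiDataset([]), 700.0)


class TestMassAccuracy:
    def test_all_on_target_gives_zero(self):
        ds = make_msi_dataset({(i, 0): [(800.0, 1.0)] for i in range(5)})
        res = hs.mass_accuracy_rmse(ds, 800.0)
        assert res.rmse_ppm == 0.0
        assert res.n_spectra == 5

    def test_constant_offset_recovered(self):
        target = 800.0
        ds = make_msi_dataset({(i, 0): [(target * (1 + 2e-6), 1.0)] for i in range(4)})
        res = hs.mass_accuracy_rmse(ds, target)
        assert res.rmse_ppm == pytest.approx(2.0, abs=1e-6)

    def test_closest_peak_selected(self):
        target = 800.0
        ds = make_msi_dataset({(0, 0): [(target * (1 - 3e-6), 1.0),
                                        (target * (1 + 1e-6), 1.0)]})
        res = hs.mass_accuracy_rmse(ds, target)
        assert res.delta_ppm[0] == pytest.approx(1.0, abs=1e-6)

    def test_missing_ion_flags_undefined(self):
        ds = make_msi_dataset({(0, 0): [(700.0, 1.0)]})
        res = hs.mass_accuracy_rmse(ds, 800.0)
        assert not res.defined
        assert res.n_spectra == 0

    def test_injected_dispersion_recovered(self, msi_phantom):
        # injected per-species ppm scatter of 1.0 comes back as the RMSE
        res = hs.mass_accuracy_rmse(msi_phantom, 788.5565, 4.0)
        assert res.defined
        assert res.rmse_ppm == pytest.approx(1.0, abs=0.15)

    def test_invariant_to_pixel_order_and_intensity_scale(self):
        rng = np.random.default_rng(0)
        peaks = {(i, 0): [(800.0 * (1 + rng.normal(0, 1e-6)), rng.uniform(1, 9))]
                 for i in range(50)}
        a = hs.mass_accuracy_rmse(make_msi_dataset(peaks), 800.0).rmse_ppm
        scaled = {k: [(mz, 100 * it) for mz, it in v]
                  for k, v in reversed(list(peaks.items()))}
        b = hs.mass_accuracy_rmse(make_msi_dataset(scaled), 800.0).rmse_ppm
        assert a == pytest.approx(b, abs=1e-12)


class TestRgbComposite:
    def _im(self, arr):
        from histospec.msi import IonImage

        return IonImage(np.asarray(arr, dtype=float), 800.0)

    def test_single_nonzero_channel_is_monochrome(self):
        z = np.zeros((2, 2))
        rgb = rgb_composite([self._im([[1, 2], [3, 4]]), self._im(z), self._im(z)])
        assert rgb[..., 1].max() == 0.0 and rgb[..., 2].max() == 0.0
        assert rgb[..., 0].max() == 1.0

    def test_identical_images_give_gray(self):
        v = [[0.0, 1.0], [2.0, 3.0]]
        rgb = rgb_composite([self._im(v)] * 3)
        assert np.allclose(rgb[..., 0], rgb[..., 1])
        assert np.allclose(rgb[..., 1], rgb[..., 2])

    def test_three_lipids_occupy_disjoint_regions(self, msi_phantom):
        ims = [hs.extract_ion_image(msi_phantom, mz)
               for mz in (868.6556, 788.5565, 748.6215)]
        rgb = rgb_composite(ims)
        # where any lipid is strong, exactly one channel dominates
        strong = rgb.max(axis=2) > 0.2
        dominant = rgb.argmax(axis=2)
        for ch in range(3):
            sel = strong & (dominant == ch)
            assert sel.any()
            others = [c for c in range(3) if c != ch]
            assert np.median(rgb[sel][:, others]) < 0.05

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rgb_composite([self._im(np.zeros((2, 2))), self._im(np.zeros((2, 2))),
                           self._im(np.zeros((3, 3)))])
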