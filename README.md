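# histospec

Multimodal spectral histology for tissue cross-sections: random-decision-forest
classification of FTIR hyperspectral images into tissue classes, MALDI mass
spectrometry imaging (MSI) analysis with ppm-binned ion images and accurate-mass
lipid identification, and metadata-driven co-registration of the two modalities.

The package targets workflows like the analysis of earthworm (*Eisenia fetida*)
cross-sections, where a fast, label-free FTIR scan first maps the anatomy —
background/embedding medium, body wall, digestive system, other tissue — and a
high-resolution MALDI-MSI measurement then localizes individual lipids within
the regions of interest that the class map defines. Because real instrument
data for such studies is rarely public, the package ships a synthetic phantom
generator that emulates the statistical structure of both modalities with known
ground truth, so the entire pipeline is testable end to end.

## The methods at its core

**Tissue classification.** Each pixel of an FTIR cube (absorbance spectrum over
3600–900 cm⁻¹) is reduced to a vector of *spectral descriptors* — baseline-
corrected band integrals, peak heights and band ratios over wavenumber windows
(700 by default). A random decision forest f: ℝᵖ → {1..4} is trained on
labelled reference spectra collected as 30 spectra per class per tissue
section over five sections (600 references). Descriptor count is optionally
reduced by iterative variable-importance elimination (drop the lowest 20% by
mean decrease in impurity, refit, stop at a target count or when the
out-of-bag score degrades).

**Validation.** Monte Carlo cross-validation: the references are split
randomly (stratified, ratio 0.9) into train/test pairs 20 times; the pooled
confusion matrix C (rows = true class, columns = predicted) yields per-class
sensitivity, specificity and precision, and the overall measures

- total accuracy  `acc = tr(C)/s`,
- Cohen's kappa  `κ = (p_o − p_e)/(1 − p_e)`, `p_e = Σ_k r_k c_k / s²`,
- extended Matthews correlation
  `MCC = (tr(C)·s − Σ_k r_k c_k) / √((s² − Σ_k c_k²)(s² − Σ_k r_k²))`,

with r_k, c_k the row/column sums and s the total count.

**MSI analysis.** Lipid shorthand such as `PC(O-36:5)` is parsed to an
elemental formula (ether PC(O-C:D) → C_{C+8}H_{2C−2D+18}NO₇P), its
monoisotopic mass M, and adduct m/z = M + m(cation) − mₑ for [M+H]⁺, [M+Na]⁺,
[M+K]⁺. Ion images sum peak intensities within a ±2.5 ppm bin; dataset mass
accuracy is the RMSE of per-pixel Δm (ppm, closest peak within ±4 ppm). The
FTIR class map is registered onto the MSI raster by the pixel-pitch ratio
(11.05 µm → 5 µm) and co-localization is quantified as the fraction of an
ion's intensity inside each class ROI and its enrichment over the ROI's area
fraction.

## Worked example

```python
import histospec as hs

# five synthetic sections, the 30-per-class labelling protocol, default bank
phantoms = [hs.generate_ftir_phantom(hs.PhantomConfig(seed=i)) for i in range(5)]
refs = hs.generate_reference_collection(phantoms, per_class=30, seed=7)
bank = hs.build_default_bank(refs.axis, 700)

model = hs.TissueClassifier(refs, bank, hs.RdfConfig(seed=3))
cv = model.monte_carlo_cv(hs.ValidationConfig(seed=11))
print(cv.summary())
```

prints

```
Monte Carlo cross-validation (ratio 0.9, 20 pairs, 1200 pooled predictions)
class              sensitivity specificity   precision
background              1.0000      1.0000      1.0000
body wall               1.0000      1.0000      1.0000
digestive system        1.0000      1.0000      1.0000
other tissue            1.0000      1.0000      1.0000
total accuracy          1.0000
Cohen kappa             1.0000
extended MCC            1.0000
```

Each of the 20 random splits trains on 540 of the 600 references and tests on
the held-out 60; the pooled confusion matrix therefore contains 1200 test
predictions. On the default phantom the four band models are well separated at
the default noise level, so all pooled measures reach 1.0. The fitted results
object also classifies whole cubes (`cv` is independent of it):

```python
res = model.fit()
cmap = res.classify_image(phantoms[0][0])        # TissueClassMap, 64x64
ds = hs.generate_msi_phantom(phantoms[0][1], seed=2)
ion = hs.extract_ion_image(ds, 788.5565)         # digestive-tract lipid
stats = hs.overlay_statistics(cmap, [ion])
print(f"{stats.fraction_inside[(3, 0)]:.4f}")    # 0.9465 of the intensity
print(f"{stats.enrichment[(3, 0)]:.4f}")         # 19.9224-fold enrichment
```

i.e. ~95% of the PC(O-36:5) [M+Na]⁺ signal (m/z 788.5565) falls inside the
predicted digestive-system ROI, a ~20-fold enrichment over that ROI's share of
the imaged area.

The same pipeline is scriptable from the shell:

```sh
histospec run-all --seed 0 --out runs/demo      # full workflow + report.json
histospec simulate --seed 1 --out runs/sim      # cubes, imzML, truth sidecars
histospec msi-accuracy --imzml runs/sim/section-1.imzML \
    --species "PC(O-36:5)" --adduct "[M+Na]+"
```

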