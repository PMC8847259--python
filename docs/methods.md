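# Methods

This note documents the models, parameter choices and numerical conventions
behind `histospec`, and what the synthetic phantoms do and do not establish
about real instrument data.

## Data model and conventions

FTIR cubes are stored as absorbance (descriptors are linear in absorbance,
which keeps band integrals additive). Pixel indices are 0-based `(row, col)`;
physical positions refer to pixel centres, with the origin at the centre of
pixel (0, 0), x growing with columns and y with rows. The default FTIR grid is
64×64 at 11.05 µm pitch (a focal-plane-array frame); the default MSI raster is
5 µm. imzML I/O translates between the standard's 1-based (x, y) convention
and the package's 0-based one, so package pixel (0, 0) is imzML (1, 1). The
hypercube container is a documented HDF5 layout (`cube`, `wavenumbers`,
grid-metadata attributes); no open FTIR-cube standard is universal enough to
adopt instead. imzML files are written in processed mode because centroided
synthetic data is sparse; continuous-mode files are read transparently.

The spectral axis defaults to 900–3600 cm⁻¹ at 4 cm⁻¹ spacing — half the
8 cm⁻¹ nominal instrument resolution, i.e. the conventional zero-filling
factor of 2. Both spacing and range are configurable.

## Synthetic phantom

The FTIR phantom is a geometric cross-section: an elliptical body (semi-axes
28×24 px), a body-wall ring (4 px thick), a digestive-tract ellipse (9×7 px,
slightly off-centre) strictly inside it, the remaining interior as "other
tissue", and everything else background. The epidermis rim is the outermost
2-px shell of the body wall; the interstitial compartment is the other-tissue
region between wall and tract. Per-pixel spectra are sums of Gaussian bands
per class, times a multiplicative gain jitter, plus a random linear baseline
and white channel noise:

```
s(ν) = g · Σ_b A_b exp(−(ν − c_b)²/2σ_b²) + m·(ν − ν₀)/Δν + ε(ν)
g ~ N(1, 0.08²),  m ~ N(0, 0.02²),  ε ~ N(0, 0.05²) per channel
```

The band tables place class contrast where mid-IR tissue contrast actually
lives — the carbohydrate/nucleic-acid fingerprint region (≈900–1450 cm⁻¹),
amide I/II (≈1500–1700 cm⁻¹) and the C–H/lipid stretch region
(≈2500–3500 cm⁻¹): background is a weak broad carbohydrate band
(embedding-medium-like), body wall is amide-dominated with moderate CH₂
stretches, digestive tissue is fingerprint-dominated with moderate amide, and
other tissue is dominated by the 1740 cm⁻¹ ester carbonyl and CH₂ bands.
Amide and fingerprint bands are deliberately shared between tissue classes at
different amplitudes so classes overlap realistically rather than living in
disjoint channels. Amplitudes are 0.05–1.0 AU; the noise defaults above are
typical of a co-added FPA measurement and were fixed once when the generator
was written.

The reference protocol samples 30 pixels per class per section uniformly
without replacement from the truth map — five sections give the standard
600-spectrum collection.

The MSI phantom covers the FTIR extent at 5 µm. In pixels whose centre falls
in a species' compartment, a peak is placed at `m/z·(1 + ε·10⁻⁶)` with
`ε ~ N(0, sd)` (default sd = 1 ppm, of the order of a well-calibrated
Orbitrap) and lognormal intensity (mean 100, CV 0.5 — strictly positive and
heavy-tailed like MALDI ion counts). Five uniform "chemical noise" peaks per
pixel (700–900 u, ≤1% of the species mean) provide a background floor. The
default panel assigns PC(O-40:1) [M+K]⁺ to the epidermis rim, PC(O-36:5)
[M+Na]⁺ to the digestive tract and PC(O-34:0) [M+H]⁺ to the interstitial
compartment.

**What the phantom does not emulate:** Mie/scattering artifacts, water-vapour
lines, detector drift, isotope envelopes, matrix clusters, intensity
dependence on matrix crystal size. Passing tests on phantoms therefore
establish correctness of the *algorithms* (feature extraction, training,
validation arithmetic, binning, registration), not instrument-level
performance on real tissue. In particular, the classifier's near-perfect CV
scores on the default phantom reflect the phantom's class separability, and
the reported figures of merit are lower-bounded, not matched, by design.

## Descriptors

The default bank tiles the axis with three families — 32 cm⁻¹ integrals,
96 cm⁻¹ integrals and 32 cm⁻¹ peak heights — with evenly spaced window starts,
split as evenly as possible to exactly `target_n` (default 700, a conventional
bank size for forest inputs on this axis). Each window uses a *local
linear-endpoint baseline* (the chord between the window's first and last
channels) rather than a global baseline: it is self-contained, robust to the
phantom's random linear baselines, and standard practice for band-descriptor
features. Heights are the maximum above the chord, areas the trapezoidal
integral above it, ratios the quotient of two areas with an ε = 10⁻¹² guard.
A window narrower than the channel spacing is widened to the minimum channel
count its statistic needs (two for baselines/areas, one for a bare height).
The bank taxonomy (heights/areas/ratios over windows) is an open
re-parameterisation: no published enumeration of a canonical 700-descriptor
set exists, so any bank of matching size and taxonomy is admissible and this
one is *a* default, not *the* reference set.

## Classifier

`TissueClassifier` wraps a random forest (scikit-learn) over the descriptor
matrix: 200 trees, `sqrt` feature subsampling, unlimited depth, fixed seed —
conventional forest defaults, all configurable. Prediction is the majority
vote; exact probability ties resolve to the lower class id (argmax over
ascending class order), which is deterministic and documented.

Variable reduction ranks features by mean decrease in impurity (the forest's
native importance; permutation importance can be substituted by the caller)
and drops the lowest 20% per iteration, clamping the last drop to land
exactly on `stop_n` (default 215). Iteration stops at `stop_n` or when the
out-of-bag score falls more than 0.02 below its running best. Because "best
scoring" is ambiguous when scores plateau, the returned bank is the *smallest*
whose out-of-bag score is within 0.02 of the best seen — a parsimony rule that
prefers the reduced bank whenever reduction is cost-free. Whether a fixed
schedule or score-based stopping produced any particular published endpoint
is not determinable, so both criteria are active simultaneously.

## Validation

Monte Carlo CV uses stratified splits by default (each class contributes
⌈0.9·n_k⌋ to training), 20 pairs at ratio 0.9. Correct/wrong predictions are
*pooled* into one confusion matrix before computing measures — per-split
accuracies are kept for diagnostics but the headline numbers come from the
pooled matrix, which weights every prediction equally. A split missing a
class in training is resampled (up to 10 attempts, logged). Measures with
zero denominators (absent class, degenerate marginals) are NaN with an
explicit `defined` flag, never silently 0. Useful identities: κ ≤ accuracy on
any valid matrix, and the extended MCC reduces to the classical binary
Matthews correlation at K = 2 — both are enforced by tests against
independent oracles (hand computation and scikit-learn's label-based
implementations).

## MSI analysis

The "±2.5 ppm bin" is read as half-width 2.5 ppm each side of the target
(the common ion-image convention), with inclusive bounds; in-bin aggregation
is a *sum* (robust for centroid data; max is configurable at the call site by
extracting narrower bins). The mass-accuracy RMSE considers every pixel with
at least one peak within ±4 ppm and takes the *closest* peak's deviation —
with multiple candidate peaks a per-spectrum Δm must be a scalar, and closest
is the only choice that is monotone in calibration error.

Lipid arithmetic embeds an 8-decimal monoisotopic mass table (C 12 exact,
H 1.00782503, N 14.00307401, O 15.99491462, P 30.97376163, Na 22.98976928,
K 38.96370668) and subtracts one electron mass (0.00054858 u) for singly
charged cations. The PC formula rule — diacyl C:D → C_{C+8}H_{2C−2D+16}NO₈P,
ether O-C:D → C_{C+8}H_{2C−2D+18}NO₇P — reproduces reference ether-PC adduct
masses to well under 1.5 ppm. Only the PC headgroup is implemented; the
parser isolates the headgroup table as the extension point.

## Co-registration

Both modalities measure the same physical section, so registration is a
similarity transform from grid metadata (pitch ratio, optional origin
offset), not feature-based image registration; labels are nominal, so
resampling is nearest-neighbour. Co-localization is operationalized as
intensity fraction inside a class ROI and enrichment over the ROI's area
fraction — an explicit quantification of what is otherwise an "the ion image
matches the class" statement; fractions over the four classes partition to 1
by construction.

## Problem sizes and determinism

Default study conditions: 5 sections × 64×64 px × 676 channels, 600
references, 700 descriptors, 20 CV pairs (1200 pooled predictions), MSI
rasters of ~20k pixels at 5 µm. The full default workflow runs in well under
a minute on one core. Every stochastic stage takes an explicit seed; the
workflow derives per-stage sub-seeds from one master seed by a stable string
hash, so identical configurations produce byte-identical reports.

## Known limitations

- Phantom realism is bounded to band-region fidelity; no claim is made that
  class spectra resemble any particular measured tissue spectrum.
- The descriptor bank is an open re-parameterisation (see above).
- Identification is by precursor accurate mass only; no MS/MS scoring,
  isotope patterns or database lookup.
- Profile-mode MSI spectra are passed through, not centroided.
- Registration assumes the metadata transform is exact; physical section
  deformation between instruments is out of scope.
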