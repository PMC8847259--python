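import numpy as np
import pytest

import histospec as hs
from histospec.synthetic import DEFAULT_LIPID_PANEL


@pytest.fixture(scope="session")
def axis():
    return hs.SpectralAxis.default()


@pytest.fixture(scope="session")
def phantom1():
    """One default-noise phantom section with its ground truth."""
    return hs.generate_ftir_phantom(hs.PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def phantoms5():
    """Five independent default phantom sections (the training protocol)."""
    return [hs.generate_ftir_phantom(hs.PhantomConfig(seed=i)) for i in range(5)]


@pytest.fixture(scope="session")
def refs600(phantoms5):
    """The 5-section x 4-class x 30-spectra reference collection."""
    return hs.generate_reference_collection(phantoms5, per_class=30, seed=7)


@pytest.fixture(scope="session")
def bank700(axis):
    return hs.build_default_bank(axis, 700)


@pytest.fixture(scope="session")
def bank150(axis):
    """Smaller bank for fast unit tests."""
    return hs.build_default_bank(axis, 150)


@pytest.fixture(scope="session")
def msi_phantom(phantom1):
    """Default three-lipid MSI phantom matched to phantom1's truth."""
    _, truth = phantom1
    return hs.generate_msi_phantom(truth, list(DEFAULT_LIPID_PANEL), seed=2)


@pytest.fixture(scope="session")
def zero_noise_pair():
    """A noise-free phantom and a classifier trained on it."""
    cfg = hs.PhantomConfig(seed=3, noise_sd=0.0, gain_jitter_sd=0.0,
                           baseline_slope_sd=0.0)
    img, truth = hs.generate_ftir_phantom(cfg)
    refs = hs.generate_reference_collection([(img, truth)], per_class=30, seed=3)
    bank = hs.build_default_bank(img.axis, 150)
    model = hs.TissueClassifier(refs, bank, hs.RdfConfig(n_trees=50, seed=3))
    return img, truth, refs, bank, model.fit()


@pytest.fixture(scope="session")
def fitted_small(phantom1):
    """Classifier trained on one default-noise section with a small bank."""
    img, truth = phantom1
    refs = hs.generate_reference_collection([(img, truth)], per_class=30, seed=5)
    bank = hs.build_default_bank(img.axis, 150)
    model = hs.TissueClassifier(refs, bank, hs.RdfConfig(n_trees=100, seed=5))
    return img, truth, refs, bank, model.fit()


def make_msi_dataset(peaks, pixel_size_um=5.0):
    """Build a small MsiDataset from {(x, y): [(mz, intensity), ...]}."""
    from histospec.hyperdata import MsiDataset, MsiPixel

    pixels = []
    for coord, plist in peaks.items():
        plist = sorted(plist)
        pixels.append(MsiPixel(coord,
                               np.array([p[0] for p in plist], dtype=float),
                               np.array([p[1] for p in plist], dtype=float)))
    return MsiDataset(pixels, pixel_size_um=pixel_size_um)
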