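import numpy as np
import pytest

from bandfuse import LabeledDataset, MultibandImage, generate
from bandfuse.synthetic import SyntheticSpec, default_signature_matrix


@pytest.fixture(scope="session")
def easy_spectral():
    """Linearly separable 13-band/10-class flat-field dataset: every
    single band orders the classes with gaps far above the noise, so any
    channel triplet is separable.  Sensor outliers are included so the
    max/10 normalization keeps its contrast."""
    rng = np.random.default_rng(5)
    sig = default_signature_matrix(10, 13, rng, base_level=140.0,
                                   band_strength=np.full(13, 80.0))
    spec = SyntheticSpec(n_classes=10, n_bands=13, height=32, width=32,
                         n_per_class=8, signature_matrix=sig, noise_sd=10.0,
                         outlier_rate=3e-3, seed=5)
    return spec, generate(spec)


@pytest.fixture(scope="session")
def microscopy_ds():
    from bandfuse import microscopy_fixture_spec
    spec = microscopy_fixture_spec(seed=3, n_per_class=4)
    return spec, generate(spec)


@pytest.fixture()
def tiny_ds():
    """Three 4-band patterns with hand-set pixels for exact I/O checks."""
    rng = np.random.default_rng(0)
    images = [MultibandImage(pixels=rng.uniform(0, 200, size=(6, 5, 4)),
                             band_ids=["b0", "b1", "b2", "b3"],
                             pattern_id=f"p{i}") for i in range(3)]
    return LabeledDataset(images=images, labels=np.array([0, 1, 0]),
                          class_names=["water", "forest"])
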