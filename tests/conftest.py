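import numpy as np
import pytest

from texens.synth import CellParams, SynthConfig, generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A random 16x16 grayscale image in [0, 255]."""
    return rng.uniform(0, 255, size=(16, 16))


@pytest.fixture(scope="session")
def tiny_params():
    return {
        "fusiform": CellParams(elongation=3.0, cell_diameter=20.0,
                               pigment=0.15),
        "epithelioid": CellParams(elongation=1.3, cell_diameter=12.0,
                                  pigment=0.25),
        "cobblestone": CellParams(elongation=1.0, cell_diameter=7.0,
                                  pigment=0.7, hexagonal=True),
    }


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The full synthetic fixture: 3 classes x 5 parents, 4x4 subwindows."""
    cfg = SynthConfig(n_parent_images=5, grid=(4, 4), seed=1)
    out = tmp_path_factory.mktemp("fixture_dataset")
    return generate_synthetic_dataset(cfg, out)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_params):
    """A small 3-class synthetic dataset: 3 parents/class, 2x2 subwindows."""
    cfg = SynthConfig(n_parent_images=3, grid=(2, 2), seed=7,
                      image_size=(96, 96), class_params=tiny_params)
    out = tmp_path_factory.mktemp("tiny_dataset")
    return generate_synthetic_dataset(cfg, out)
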