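import numpy as np
import pytest

from foldlight import PhantomSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20251234)


@pytest.fixture(scope="session")
def clean_phantom():
    """256x256 phantom, no nuclei, default (tight) color spreads."""
    spec = PhantomSpec(height=256, width=256, nuclei_density=0.0, seed=7)
    img, fold_mask, nuclei_mask = generate(spec)
    return spec, img, fold_mask, nuclei_mask


@pytest.fixture(scope="session")
def nuclei_phantom():
    """256x256 phantom with 5% nuclei speckle, the confounder case."""
    spec = PhantomSpec(height=256, width=256, nuclei_density=0.05, seed=11)
    img, fold_mask, nuclei_mask = generate(spec)
    return spec, img, fold_mask, nuclei_mask


def random_images(seed, n, size):
    """n random size x size RGB images, uniform on the cube."""
    gen = np.random.default_rng(seed)
    return gen.random((n, size, size, 3))
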