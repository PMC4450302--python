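import numpy as np
import pytest

from angioseed import phantom as ph
from angioseed.vesselness import multiscale_vesselness


@pytest.fixture(scope="session")
def clean_tube():
    """Noise-free straight horizontal tube, radius 3, 128x128."""
    spec = ph.straight_tube(size=(128, 128), radius=3.0, depth=100.0, noise_sigma=0.0)
    image, truth = ph.generate(spec)
    return image, truth


@pytest.fixture(scope="session")
def clean_tube_vesselness(clean_tube):
    image, _ = clean_tube
    return multiscale_vesselness(image)


@pytest.fixture(scope="session")
def clean_bifurcation():
    """Noise-free 3-branch bifurcation phantom, 512x512."""
    spec = ph.bifurcation(noise_sigma=0.0)
    image, truth = ph.generate(spec)
    return image, truth


@pytest.fixture(scope="session")
def noisy_bifurcation():
    """Standard 3-branch phantom: 512x512, radii 2.5-5, contrast/noise = 5, seed 42."""
    spec = ph.bifurcation()
    image, truth = ph.generate(spec)
    return image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
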