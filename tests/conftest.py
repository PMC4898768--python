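import numpy as np
import pytest

from endoquant import simgen
from endoquant.psf import spot_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_noise():
    """Pure additive Gaussian read noise, sd 10 (no Poisson component)."""
    return simgen.NoiseModel(read_noise_sd=10.0, photon_scale=0.0)


def make_spot_patch(
    amplitude: float,
    sigma: float = 1.4,
    size: int = 9,
    background: float = 100.0,
    noise_sd: float = 0.0,
    offset: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Single pixel-integrated Gaussian spot near the patch center."""
    c = size // 2
    x0, y0 = c + offset[0], c + offset[1]
    patch = background + spot_image(np.arange(size), np.arange(size), x0, y0,
                                    amplitude, sigma)
    if noise_sd > 0:
        patch = patch + (rng or np.random.default_rng(0)).normal(0, noise_sd, patch.shape)
    return patch, (x0, y0)
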