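import numpy as np
import pytest
from scipy import ndimage

from epidqa import ImageGrid, SimConfig


@pytest.fixture(scope="session")
def full_config() -> SimConfig:
    """Default study conditions on the full 512x384 panel."""
    return SimConfig()


@pytest.fixture(scope="session")
def controlled_config() -> SimConfig:
    """Recovery-test conditions: over-response on, every other distortion off
    (backscatter, scatter, sensitivity, noise, dark), on a reduced panel."""
    return SimConfig(
        n_x=256,
        n_y=192,
        pitch_mm=1.5625,
        backscatter_amplitude=0.0,
        scatter_fraction=0.0,
        sensitivity_amplitude=0.0,
        noise_sigma=0.0,
        dark_level=0.0,
        dark_jitter=0.0,
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Coarse panel (same 40x30 cm physical area) for gamma-heavy runs."""
    return SimConfig(n_x=160, n_y=120, pitch_mm=2.5)


def smooth_field(rng: np.random.Generator, amplitude: float, sigma_px: float,
                 shape=(16, 16)) -> np.ndarray:
    """Smooth zero-mean random field scaled to the given peak amplitude."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    return amplitude * f / np.abs(f).max()


def plateau_pair(rng: np.random.Generator, shape=(16, 16), pitch_mm: float = 0.78125):
    """A reference/evaluated pair shaped like portal-image plateaus: a gentle
    base field (+-3%) and a smooth dose perturbation (+-5%)."""
    base = 1.0 + smooth_field(rng, 0.03, 2.0, shape)
    evaluated = base * (1.0 + smooth_field(rng, 0.05, 2.0, shape))
    return ImageGrid(base, pitch_mm), ImageGrid(evaluated, pitch_mm)
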