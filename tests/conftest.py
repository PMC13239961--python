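import numpy as np
import pytest

from rotqa import DosePlane, DetectorSpec, PlanSpec, generate_plan, extract_plane
from rotqa.preprocess import standardize


@pytest.fixture(scope="session")
def small_plan():
    """One deterministic synthetic plan (48^3 at 2 mm) with its mask."""
    return generate_plan(PlanSpec(), seed=42)


@pytest.fixture(scope="session")
def noise_free_plane(small_plan):
    volume, _ = small_plan
    return extract_plane(volume, DetectorSpec(noise_sd_frac=0.0))


@pytest.fixture(scope="session")
def standardized_plane(noise_free_plane):
    return standardize(noise_free_plane)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_plane(rng, n=15, spacing=2.0, smooth=2.0):
    """Smooth positive random plane helper used across metric tests."""
    from scipy import ndimage

    m = ndimage.gaussian_filter(rng.random((n, n)), smooth)
    m -= m.min()
    m /= m.max()
    return DosePlane(m, spacing_mm=spacing)
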