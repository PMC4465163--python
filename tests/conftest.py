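import numpy as np
import pytest

from pettex import PETVolume, PhantomParams, generate_tumor_phantom


@pytest.fixture
def flat_phantom() -> PETVolume:
    """A perfectly homogeneous 30 mm tumor: no texture, no noise."""
    return generate_tumor_phantom(PhantomParams(
        heterogeneity_amplitude=0.0, noise_sd=0.0, seed=0))


@pytest.fixture
def textured_phantom() -> PETVolume:
    return generate_tumor_phantom(PhantomParams(
        heterogeneity_amplitude=1.5, noise_sd=0.1, seed=11))


def random_voi(rng: np.random.Generator, max_side: int = 8, n_bins: int = 6):
    """A random small gray-level grid with a random (guaranteed non-trivial)
    mask, for oracle-equivalence checks."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    bins = rng.integers(1, n_bins + 1, size=shape)
    mask = rng.random(shape) < rng.uniform(0.4, 0.9)
    if mask.sum() < 2:
        mask[tuple(np.argwhere(~mask)[0])] = True
        mask[tuple(np.argwhere(~mask)[0])] = True
    return bins.astype(np.int64), mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150422)
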