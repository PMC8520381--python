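import numpy as np
import pytest

from sdss import ArrayGeometry, SourceSet, simulate_snapshots


def random_hermitian_psd(rng: np.random.Generator, m: int) -> np.ndarray:
    """Random Hermitian PSD matrix via X X^H with X taller than square."""
    x = rng.standard_normal((m, 2 * m)) + 1j * rng.standard_normal((m, 2 * m))
    return x @ x.conj().T / (2 * m)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    return ArrayGeometry(num_elements=8, num_subarrays=3)


@pytest.fixture
def two_source_frame(small_geometry):
    sources = SourceSet(angles=np.array([-0.2, 0.25]),
                        amplitudes=np.array([1.0, 1.0]))
    return simulate_snapshots(small_geometry, sources, noise_variance=0.05,
                              num_snapshots=256, seed=7)
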