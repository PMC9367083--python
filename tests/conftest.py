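import numpy as np
import pytest

from radcine.phantom import PhantomConfig, make_cardiac_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 64-px, 8-frame, 4-coil phantom shared across tests."""
    cfg = PhantomConfig(matrix_size=64, n_frames=8, n_coils=4, noise_sd=0.0, seed=3)
    return make_cardiac_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_ndft(image: np.ndarray, kcoords: np.ndarray) -> np.ndarray:
    """O(N^2 M) direct-summation non-uniform DFT oracle (image center at n//2)."""
    n = image.shape[0]
    c = n // 2
    xs, ys = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    out = np.empty(len(kcoords), dtype=np.complex128)
    for i, (kx, ky) in enumerate(kcoords):
        out[i] = np.sum(image * np.exp(-1j * (kx * xs + ky * ys)))
    return out
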