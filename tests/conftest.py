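import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hermitian(rng, n, scale=1.0):
    """Stack of n generic 4x4 Hermitian matrices (indefinite in general)."""
    a = rng.normal(size=(n, 4, 4)) + 1j * rng.normal(size=(n, 4, 4))
    return scale * (a + np.conj(np.swapaxes(a, -1, -2))) / 2.0


def random_gram_psd(rng, n, rank=4):
    """Stack of n PSD coherency-like matrices H = G G*, trace 1."""
    g = rng.normal(size=(n, 4, rank)) + 1j * rng.normal(size=(n, 4, rank))
    h = g @ np.conj(np.swapaxes(g, -1, -2))
    tr = np.einsum("nii->n", h).real
    return h / tr[:, None, None]
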