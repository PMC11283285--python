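"""Synthetic Mueller matrices and images with exact ground truth.

Generators for (a) random physically realizable Mueller matrices, built as
Gram coherency matrices H = G G* (positive semidefinite by construction)
and mapped back through the Pauli-basis inversion; (b) tissue-like
diagonal-depolarizer matrices diag(1, a, a, b) with a closed-form spectrum;
(c) Gaussian measurement noise on the matrix elements; and (d) whole images
with a planted, margin-enforced set of nonphysical pixels, so filtering can
be validated against an exact truth mask without any experimental data.

Randomness is drawn from per-row Philox streams keyed on (seed, row), with
pixels generated in column order, so the data depend only on the seed and
the pixel position -- never on chunking or worker counts downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .checks import Tolerance
from .core import coherency_from_mueller, mueller_from_coherency
from .filter import MuellerImage, RealizabilityMask

__all__ = [
    "SynthSpec",
    "random_physical_mueller",
    "tissue_like_mueller",
    "perturb_mueller",
    "synth_image",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic Mueller image.

    ``frac_nonphysical`` is the planted fraction of nonphysical pixels;
    ``noise_sigma`` the standard deviation of additive Gaussian noise per
    m00-normalized element (experimental systems reach below 0.01);
    ``rank`` the rank of the generated coherency matrices (4 = generic
    depolarizing sample).
    """

    rows: int
    cols: int
    frac_nonphysical: float = 0.0
    noise_sigma: float = 0.0
    rank: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not 0.0 <= self.frac_nonphysical <= 1.0:
            raise ValueError("frac_nonphysical must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 1 <= self.rank <= 4:
            raise ValueError("rank must be in 1..4")


def _row_rng(seed: int, row: int) -> np.random.Generator:
    """Counter-style stream: independent Philox generator per (seed, row)."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=(row,)))
    )


def _gram_coherency(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """n random PSD coherency matrices H = G G*, trace-normalized to 1."""
    g = rng.standard_normal((n, 4, rank)) + 1j * rng.standard_normal((n, 4, rank))
    h = g @ np.conj(np.swapaxes(g, -1, -2))
    tr = np.einsum("...ii->...", h).real
    return h / tr[:, None, None]


def random_physical_mueller(rank: int = 4, seed: int = 0, rng=None):
    """One random physically realizable Mueller matrix.

    Draws a complex 4 x rank factor G with standard-normal real and
    imaginary parts, forms the Gram matrix H = G G* (PSD by construction,
    rank <= ``rank``), rescales to trace 1 (so m00 = 1), and inverts the
    Pauli expansion.  Returns ``(M, H)``.
    """
    if not 1 <= rank <= 4:
        raise ValueError("rank must be in 1..4")
    if rng is None:
        rng = np.random.default_rng(seed)
    h = _gram_coherency(rng, 1, rank)[0]
    return mueller_from_coherency(h), h


def tissue_like_mueller(a: float, b: float) -> np.ndarray:
    """Diagonal depolarizer diag(1, a, a, b) mimicking m00-normalized tissue.

    Its coherency matrix has the closed-form spectrum
    { (1 + 2a + b)/4, (1 - 2a + b)/4, (1 - b)/4, (1 - b)/4 },
    so for 0 <= a, b <= 1 the matrix is physical iff 1 - 2a + b >= 0; the
    realizability boundary of the family is the line 1 - 2a + b = 0.
    """
    return np.diag([1.0, float(a), float(a), float(b)])


def perturb_mueller(m: np.ndarray, noise_sigma: float, seed: int = 0, rng=None):
    """Add i.i.d. Gaussian noise (sd = noise_sigma * m00) to all 16 elements."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    m = np.asarray(m, dtype=np.float64)
    if noise_sigma == 0:
        return m.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    scale = noise_sigma * abs(float(m[..., 0, 0]))
    return m + rng.normal(0.0, scale, size=m.shape)


def _lambda_min(m: np.ndarray) -> np.ndarray:
    return np.linalg.eigvalsh(coherency_from_mueller(m))[..., 0]


def synth_image(spec: SynthSpec, tol: Tolerance = Tolerance(), margin_factor: float = 10.0):
    """Synthetic Mueller image with an exact planted realizability mask.

    Physical pixels are rank-``spec.rank`` Gram coherency matrices; a seeded
    random subset of exactly ``round(frac_nonphysical * rows * cols)``
    pixels is made nonphysical by subtracting a scaled projector onto the
    smallest-eigenvalue direction (rank-one negative perturbation with a
    controllable violation depth), then renormalizing the trace to 1.

    Every pixel is margin-enforced by rejection sampling: after optional
    Gaussian noise, the smallest coherency eigenvalue of a physical pixel
    is >= ``margin_factor * tau`` and of a planted pixel <=
    ``-margin_factor * tau`` (tau from ``tol`` at unit trace), so the truth
    mask is exact and every boundary-respecting test must recover it.

    Returns ``(MuellerImage, RealizabilityMask)`` with ``method='planted'``.
    """
    rows, cols = spec.rows, spec.cols
    n_bad = int(round(spec.frac_nonphysical * rows * cols))
    master = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xB0A,)))
    )
    flat_bad = master.choice(rows * cols, size=n_bad, replace=False)
    truth = np.ones((rows, cols), dtype=bool)
    truth.flat[flat_bad] = False

    tau = tol.tau(1.0)
    margin = margin_factor * tau
    data = np.empty((rows, cols, 4, 4), dtype=np.float64)

    for r in range(rows):
        rng = _row_rng(spec.seed, r)
        h = _gram_coherency(rng, cols, spec.rank)
        bad = ~truth[r]
        if bad.any():
            lam, vec = np.linalg.eigh(h[bad])
            v = vec[..., :, 0]
            # violation depth: uniform in [1e-3, 1e-2] of the (unit) trace
            depth = rng.uniform(1e-3, 1e-2, size=int(bad.sum()))
            shift = lam[..., 0] + depth
            h[bad] = h[bad] - shift[:, None, None] * (
                v[..., :, None] * np.conj(v)[..., None, :]
            )
            tr = np.einsum("...ii->...", h[bad]).real
            h[bad] = h[bad] / tr[:, None, None]
        m_row = mueller_from_coherency(h)
        if spec.noise_sigma > 0:
            m_row = m_row + rng.normal(0.0, spec.noise_sigma, size=m_row.shape)

        # rejection sampling until every pixel clears the margin on the
        # correct side of the boundary
        for _ in range(200):
            lmin = _lambda_min(m_row)
            ok = np.where(truth[r], lmin >= margin, lmin <= -margin)
            if ok.all():
                break
            idx = np.flatnonzero(~ok)
            h_new = _gram_coherency(rng, idx.size, spec.rank)
            redo_bad = ~truth[r][idx]
            if redo_bad.any():
                sub = h_new[redo_bad]
                lam, vec = np.linalg.eigh(sub)
                v = vec[..., :, 0]
                depth = rng.uniform(1e-3, 1e-2, size=int(redo_bad.sum()))
                shift = lam[..., 0] + depth
                sub = sub - shift[:, None, None] * (
                    v[..., :, None] * np.conj(v)[..., None, :]
                )
                tr = np.einsum("...ii->...", sub).real
                h_new[redo_bad] = sub / tr[:, None, None]
            m_new = mueller_from_coherency(h_new)
            if spec.noise_sigma > 0:
                m_new = m_new + rng.normal(0.0, spec.noise_sigma, size=m_new.shape)
            m_row[idx] = m_new
        else:
            raise RuntimeError(
                f"margin enforcement did not converge in row {r}; "
                "noise_sigma is likely too large for the requested margin"
            )
        data[r] = m_row

    img = MuellerImage(data=data, invalid_mask=np.zeros((rows, cols), dtype=bool))
    mask = RealizabilityMask(
        physical=truth,
        method="planted",
        criterion="semidefinite",
        tolerance=tol,
    )
    return img, mask
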