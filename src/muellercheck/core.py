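"""Pauli-basis algebra, coherency-matrix construction, and Stokes utilities.

A Mueller matrix ``M`` is the 4x4 real transfer matrix of an optical sample:
it maps the Stokes vector of incident light to the Stokes vector of the
outgoing light, ``S_out = M @ S_in``.  Associated with every Mueller matrix
is a 4x4 Hermitian coherency matrix

    H = (1/4) * sum_ij  m_ij * (sigma_i  (x)  sigma_j^T)

where ``sigma_0..sigma_3`` is the extended Pauli set and ``(x)`` the
Kronecker product.  ``M`` is physically realizable -- it maps every valid
Stokes vector to a valid one -- if and only if ``H`` is positive
semidefinite.  This module provides the basis, the forward map, its exact
inverse (via basis orthogonality), and small Stokes helpers used for
validation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PAULI",
    "pauli_basis",
    "coherency_from_mueller",
    "mueller_from_coherency",
    "stokes_transform",
    "degree_of_polarization",
]

#: Extended Pauli set: identity, then the three Pauli matrices in the
#: conventional polarimetric order (sigma_3 = [[0,-i],[i,0]]).
PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=np.complex128,
)


def _build_basis() -> np.ndarray:
    """The 16 Hermitian basis matrices B_ij = sigma_i (x) sigma_j^T."""
    basis = np.empty((4, 4, 4, 4), dtype=np.complex128)
    for i in range(4):
        for j in range(4):
            basis[i, j] = np.kron(PAULI[i], PAULI[j].T)
    return basis


_BASIS = _build_basis()
_BASIS.setflags(write=False)

#: Hermiticity tolerance accepted by :func:`mueller_from_coherency`.
HERMITICITY_ATOL = 1e-10


def pauli_basis() -> np.ndarray:
    """Return the 16 basis matrices ``B_ij`` as an array of shape (4,4,4,4).

    ``pauli_basis()[i, j]`` is the Hermitian 4x4 matrix
    ``sigma_i (x) sigma_j^T``.  The basis is trace-orthogonal:
    ``trace(B_ij @ B_kl) = 4`` iff ``(i,j) == (k,l)`` and 0 otherwise, and
    ``trace(B_ij) = 4`` iff ``i == j == 0``.
    """
    return _BASIS


def _validate_mueller(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.shape[-2:] != (4, 4):
        raise ValueError(f"Mueller matrix must have shape (..., 4, 4), got {m.shape}")
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))
        i, j = bad[0][-2], bad[0][-1]
        raise ValueError(f"non-finite Mueller element m[{i}][{j}]")
    return m


def coherency_from_mueller(m: np.ndarray) -> np.ndarray:
    """Hermitian coherency matrix of a Mueller matrix.

    Computes ``H = (1/4) sum_ij m_ij B_ij``.  Accepts a single (4, 4) real
    matrix or a batch (..., 4, 4); the result has the same leading shape
    with complex128 entries.  ``trace(H) == m[0, 0]`` and the map is linear
    in ``m``.

    Raises
    ------
    ValueError
        If the input has a wrong shape or contains non-finite entries.
    """
    m = _validate_mueller(m)
    return np.einsum("...ij,ijab->...ab", m, _BASIS) / 4.0


def mueller_from_coherency(h: np.ndarray, atol: float = HERMITICITY_ATOL) -> np.ndarray:
    """Invert the coherency map: ``m_ij = Re trace(H @ B_ij)``.

    Exact inverse of :func:`coherency_from_mueller` by trace-orthogonality
    of the basis.  The input must be Hermitian to within ``atol``
    (elementwise, absolute); the imaginary residue of each recovered
    element must be below 1e-10 or a ValueError is raised.
    """
    h = np.asarray(h, dtype=np.complex128)
    if h.shape[-2:] != (4, 4):
        raise ValueError(f"coherency matrix must have shape (..., 4, 4), got {h.shape}")
    herm_err = np.abs(h - np.conj(np.swapaxes(h, -1, -2))).max()
    if herm_err > atol:
        raise ValueError(
            f"input is not Hermitian: max |H - H*| = {herm_err:.3e} > {atol:.1e}"
        )
    m = np.einsum("...ab,ijba->...ij", h, _BASIS)
    resid = np.abs(m.imag).max()
    if resid > 1e-10:
        raise ValueError(f"imaginary residue {resid:.3e} exceeds 1e-10")
    return np.ascontiguousarray(m.real)


def stokes_transform(m: np.ndarray, s_in: np.ndarray) -> np.ndarray:
    """Output Stokes vector ``S_out = M @ S_in``."""
    m = _validate_mueller(m)
    s_in = np.asarray(s_in, dtype=np.float64)
    return m @ s_in


def degree_of_polarization(s: np.ndarray) -> float:
    """Degree of polarization ``rho = sqrt(S1^2 + S2^2 + S3^2) / S0``.

    0 for totally depolarized light, 1 for fully polarized light.  The
    value is deliberately not clamped to [0, 1]: values above 1 signal a
    nonphysical Stokes vector and should remain observable.

    Raises
    ------
    ValueError
        If ``S0 <= 0``.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.shape[-1] != 4:
        raise ValueError(f"Stokes vector must have length 4, got shape {s.shape}")
    s0 = s[..., 0]
    if np.any(s0 <= 0):
        raise ValueError("degree of polarization undefined for S0 <= 0")
    return np.sqrt(s[..., 1] ** 2 + s[..., 2] ** 2 + s[..., 3] ** 2) / s0
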