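"""Realizability tests on a single coherency / Mueller matrix.

Five algorithms decide whether the Hermitian coherency matrix H of a
measured Mueller matrix is positive (semi-)definite:

* ``check_eigenvalues`` -- all eigenvalues nonnegative (the classical test;
  also returns the spectrum for downstream depolarization metrics);
* ``check_cholesky``    -- the H = L L* factorization succeeds with positive
  pivots (strict definiteness only);
* ``check_sylvester``   -- all four leading principal minors positive
  (strict definiteness only);
* ``check_cp``          -- all coefficients of f(lambda) = det(H + lambda I)
  nonnegative (Descartes' rule of signs on the reflected characteristic
  polynomial), with the coefficients obtained either by direct expansion in
  the entries of H (`variant='direct'`) or from the trace power sums
  tr(H)..tr(H^4) evaluated in closed form directly on the Mueller elements
  and converted through Newton's identities (`variant='pauli'`).

All thresholds are controlled by a :class:`Tolerance`; quantities of
polynomial degree k in H (minors, CP coefficients) are compared against
``max(abs_tol, rel_tol * |trace H|^k)`` so that verdicts are invariant
under intensity rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .core import coherency_from_mueller

__all__ = [
    "Tolerance",
    "Verdict",
    "CholeskyResult",
    "check_eigenvalues",
    "check_cholesky",
    "sylvester_minors",
    "check_sylvester",
    "cp_coefficients_direct",
    "trace_powers_pauli",
    "cp_from_traces",
    "check_cp",
    "METHODS",
]

METHODS = _kernels.METHODS

SEMIDEFINITE = "semidefinite"
STRICT = "strictly_definite"


@dataclass(frozen=True)
class Tolerance:
    """Numerical threshold for realizability verdicts.

    The effective threshold for a degree-k quantity with trace scale t is
    ``tau_k = max(abs_tol, rel_tol * |t|^k)``.  Defaults suit m00-normalized
    (unit-scale) experimental data.
    """

    abs_tol: float = 1e-12
    rel_tol: float = 1e-9

    def __post_init__(self):
        if self.abs_tol < 0 or self.rel_tol < 0:
            raise ValueError("tolerances must be nonnegative")

    def tau(self, scale: float, degree: int = 1) -> float:
        return max(self.abs_tol, self.rel_tol * abs(scale) ** degree)


@dataclass(frozen=True)
class Verdict:
    """Outcome of one realizability test.

    ``witness`` is the quantity that decided: the smallest eigenvalue, the
    first nonpositive Cholesky pivot, the first nonpositive leading minor,
    or the most violating CP coefficient.
    """

    physical: bool
    criterion: str
    witness: float
    method: str


@dataclass(frozen=True)
class CholeskyResult:
    success: bool
    pivots: tuple  # diagonal entries of L, in elimination order, up to failure
    failure_index: Optional[int] = None


def _as_single_h(h) -> np.ndarray:
    h = np.asarray(h, dtype=np.complex128)
    if h.shape != (4, 4):
        raise ValueError(f"expected a single 4x4 matrix, got shape {h.shape}")
    herm_err = np.abs(h - h.conj().T).max()
    if herm_err > 1e-8:
        raise ValueError(f"matrix is not Hermitian: max |H - H*| = {herm_err:.3e}")
    return h


def check_eigenvalues(h, tol: Tolerance = Tolerance(), criterion: str = SEMIDEFINITE):
    """Eigenvalue test.  Returns ``(Verdict, spectrum)``.

    The spectrum is returned in descending order, for reuse as input to
    eigenvalue-based depolarization metrics.
    """
    h = _as_single_h(h)
    lam = np.linalg.eigvalsh(h)
    if not np.all(np.isfinite(lam)):
        raise ArithmeticError("eigensolver did not converge to finite eigenvalues")
    lmin = float(lam[0])
    tau = tol.tau(float(h.trace().real))
    if criterion == SEMIDEFINITE:
        physical = lmin >= -tau
    elif criterion == STRICT:
        physical = lmin > tau
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return Verdict(bool(physical), criterion, lmin, "eig"), lam[::-1].copy()


def check_cholesky(h, tol: Tolerance = Tolerance()):
    """Cholesky test (strict positive definiteness only).

    Returns ``(Verdict, CholeskyResult)``.  A pivot is accepted when its
    pre-square-root value exceeds the effective threshold; the elimination
    stops at the first failure.  A singular PSD matrix is reported
    nonphysical by this test -- it decides definiteness, not
    semidefiniteness.
    """
    h = _as_single_h(h)
    tau = tol.tau(float(h.trace().real))
    a = h.copy()
    pivots = []
    for k in range(4):
        dk = a[k, k].real
        if dk <= tau:
            return (
                Verdict(False, STRICT, float(dk), "chol"),
                CholeskyResult(False, tuple(pivots), failure_index=k),
            )
        pivots.append(float(np.sqrt(dk)))
        if k < 3:
            col = a[k + 1:, k]
            a[k + 1:, k + 1:] -= np.outer(col, col.conj()) / dk
    min_pre = min(p * p for p in pivots)
    return (
        Verdict(True, STRICT, float(min_pre), "chol"),
        CholeskyResult(True, tuple(pivots)),
    )


def sylvester_minors(h) -> np.ndarray:
    """Leading principal minors Delta_1..Delta_4 of a Hermitian matrix.

    Computed from committed closed-form expansions (no generic determinant
    routine); each minor is real by Hermiticity.
    """
    h = _as_single_h(h)
    return _kernels.sylvester_minors_batch(h[None])[0]


def check_sylvester(h, tol: Tolerance = Tolerance()):
    """Sylvester's criterion (strict positive definiteness only).

    Physical iff every leading principal minor Delta_k exceeds the
    degree-scaled threshold ``max(abs_tol, rel_tol * |trace|^k)``;
    short-circuits at the first failing minor.
    """
    h = _as_single_h(h)
    t = float(h.trace().real)
    minors = _kernels.sylvester_minors_batch(h[None])[0]
    for k in range(4):
        tau_k = tol.tau(t, degree=k + 1)
        if minors[k] <= tau_k:
            return Verdict(False, STRICT, float(minors[k]), "sylvester")
    return Verdict(True, STRICT, float(minors.min()), "sylvester")


def cp_coefficients_direct(h) -> np.ndarray:
    """Coefficients e1..e4 of f(lambda) = det(H + lambda I), direct expansion.

    e1 = trace(H); e2, e3 = sums of 2x2 / 3x3 principal minors; e4 = det(H).
    Each e_k equals the k-th elementary symmetric polynomial of the
    eigenvalues.
    """
    h = _as_single_h(h)
    return _kernels.cp_coefficients_batch(h[None])[0]


def trace_powers_pauli(m, return_intermediates: bool = False):
    """Power sums p_k = trace(H^k), k = 1..4, straight from Mueller elements.

    Uses the closed-form Pauli-trace expressions (p1 = m00,
    p2 = (1/4) sum m_ij^2, and the degree-3/4 forms built from det M,
    det of the lower-right 3x3 block, the row sums of squares S_i and the
    cross terms A, B, P_ij, C, D, F).  The coherency matrix is never formed.

    With ``return_intermediates=True`` also returns the named intermediate
    quantities as a dict.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (4, 4):
        raise ValueError(f"expected a single 4x4 Mueller matrix, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite Mueller element")
    if return_intermediates:
        p, inter = _kernels.trace_powers_batch(m[None], return_intermediates=True)
        return p[0], {k: float(np.asarray(v)[0]) for k, v in inter.items()}
    return _kernels.trace_powers_batch(m[None])[0]


def cp_from_traces(p):
    """Newton's identities: elementary symmetric e1..e4 from power sums p1..p4.

    Works elementwise on exact types too (Fractions stay exact: every
    division is by 2, 6 or 24 after integer-coefficient combinations).
    """
    p1, p2, p3, p4 = p
    e1 = p1
    e2 = (p1 * p1 - p2) / 2
    e3 = (p1 * p1 * p1 - 3 * p1 * p2 + 2 * p3) / 6
    e4 = (p1 ** 4 - 6 * p1 * p1 * p2 + 3 * p2 * p2 + 8 * p1 * p3 - 6 * p4) / 24
    return np.asarray([e1, e2, e3, e4])


def check_cp(
    m,
    variant: str = "pauli",
    tol: Tolerance = Tolerance(),
    criterion: str = SEMIDEFINITE,
):
    """Characteristic-polynomial test on a Mueller matrix.

    ``variant='direct'`` builds H and expands the coefficients in its
    entries; ``variant='pauli'`` computes the trace power sums in closed
    form on M and applies Newton's identities.  Physical iff every
    coefficient satisfies ``e_k >= -tau_k`` (semidefinite) or
    ``e_k > tau_k`` (strict), with the degree-k threshold
    ``tau_k = max(abs_tol, rel_tol * |m00|^k)``.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (4, 4):
        raise ValueError(f"expected a single 4x4 Mueller matrix, got {m.shape}")
    if variant not in ("direct", "pauli"):
        raise ValueError(f"unknown variant {variant!r}; use 'direct' or 'pauli'")
    method = "cp_direct" if variant == "direct" else "cp_pauli"
    physical, witness = _kernels.classify_batch(m[None], method, tol, criterion)
    return Verdict(bool(physical[0]), criterion, float(witness[0]), method)
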