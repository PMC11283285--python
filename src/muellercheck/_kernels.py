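"""Batched numerical kernels for the realizability tests.

Everything here operates on stacks: Mueller matrices as float64 arrays of
shape (n, 4, 4) and coherency matrices as complex128 arrays of shape
(n, 4, 4).  Determinants, leading principal minors and characteristic-
polynomial coefficients are computed from committed closed-form expansions
in the matrix entries (no generic determinant/eigenvalue routine in the
per-pixel hot path except for the eigenvalue method itself, whose whole
point is the dense solve).  Regression tests pin every expansion to generic
numpy oracles.
"""

from __future__ import annotations

import numpy as np

from .core import coherency_from_mueller

METHODS = ("eig", "chol", "sylvester", "cp_direct", "cp_pauli")

#: Default criterion per method.  Eigenvalue and CP-coefficient tests decide
#: positive SEMI-definiteness (the exact realizability condition); Cholesky
#: and Sylvester only support strict definiteness.
DEFAULT_CRITERION = {
    "eig": "semidefinite",
    "chol": "strictly_definite",
    "sylvester": "strictly_definite",
    "cp_direct": "semidefinite",
    "cp_pauli": "semidefinite",
}


# ---------------------------------------------------------------------------
# closed-form determinants
# ---------------------------------------------------------------------------

def _det3(a00, a01, a02, a10, a11, a12, a20, a21, a22):
    """3x3 determinant by Sarrus' rule (works for real or complex arrays)."""
    return (
        a00 * (a11 * a22 - a12 * a21)
        - a01 * (a10 * a22 - a12 * a20)
        + a02 * (a10 * a21 - a11 * a20)
    )


def det3_batch(a: np.ndarray) -> np.ndarray:
    """Determinants of a stack of 3x3 matrices."""
    return _det3(
        a[..., 0, 0], a[..., 0, 1], a[..., 0, 2],
        a[..., 1, 0], a[..., 1, 1], a[..., 1, 2],
        a[..., 2, 0], a[..., 2, 1], a[..., 2, 2],
    )


def det4_batch(a: np.ndarray) -> np.ndarray:
    """Determinants of a stack of 4x4 matrices, cofactor expansion on row 0."""
    m0 = _det3(
        a[..., 1, 1], a[..., 1, 2], a[..., 1, 3],
        a[..., 2, 1], a[..., 2, 2], a[..., 2, 3],
        a[..., 3, 1], a[..., 3, 2], a[..., 3, 3],
    )
    m1 = _det3(
        a[..., 1, 0], a[..., 1, 2], a[..., 1, 3],
        a[..., 2, 0], a[..., 2, 2], a[..., 2, 3],
        a[..., 3, 0], a[..., 3, 2], a[..., 3, 3],
    )
    m2 = _det3(
        a[..., 1, 0], a[..., 1, 1], a[..., 1, 3],
        a[..., 2, 0], a[..., 2, 1], a[..., 2, 3],
        a[..., 3, 0], a[..., 3, 1], a[..., 3, 3],
    )
    m3 = _det3(
        a[..., 1, 0], a[..., 1, 1], a[..., 1, 2],
        a[..., 2, 0], a[..., 2, 1], a[..., 2, 2],
        a[..., 3, 0], a[..., 3, 1], a[..., 3, 2],
    )
    return (
        a[..., 0, 0] * m0 - a[..., 0, 1] * m1
        + a[..., 0, 2] * m2 - a[..., 0, 3] * m3
    )


# ---------------------------------------------------------------------------
# Sylvester minors and CP coefficients from H
# ---------------------------------------------------------------------------

def _herm_det3(a, b, c, d, e, f):
    """det of Hermitian [[a, b, c], [b*, d, e], [c*, e*, f]], a/d/f real."""
    return (
        a * d * f
        - a * np.abs(e) ** 2
        - f * np.abs(b) ** 2
        - d * np.abs(c) ** 2
        + 2.0 * (b * e * np.conj(c)).real
    )


def sylvester_minors_batch(h: np.ndarray) -> np.ndarray:
    """Leading principal minors (Delta_1..Delta_4) of Hermitian stacks.

    Returns a real array of shape (..., 4).
    """
    h00 = h[..., 0, 0].real
    h11 = h[..., 1, 1].real
    h22 = h[..., 2, 2].real
    d1 = h00
    d2 = h00 * h11 - np.abs(h[..., 0, 1]) ** 2
    d3 = _herm_det3(h00, h[..., 0, 1], h[..., 0, 2], h11, h[..., 1, 2], h22)
    d4 = det4_batch(h).real
    return np.stack([d1, d2, d3, d4], axis=-1)


def cp_coefficients_batch(h: np.ndarray) -> np.ndarray:
    """Coefficients e1..e4 of f(lambda) = det(H + lambda I).

    e_k is the k-th elementary symmetric polynomial of the eigenvalues:
    e1 = trace, e2 = sum of 2x2 principal minors, e3 = sum of 3x3 principal
    minors, e4 = det(H).  Real array of shape (..., 4).
    """
    d = np.stack([h[..., i, i].real for i in range(4)], axis=-1)
    e1 = d.sum(axis=-1)
    e2 = np.zeros_like(e1)
    for i in range(4):
        for j in range(i + 1, 4):
            e2 += d[..., i] * d[..., j] - np.abs(h[..., i, j]) ** 2
    e3 = np.zeros_like(e1)
    for k in range(4):
        idx = [i for i in range(4) if i != k]
        a, b, c = idx
        e3 += _herm_det3(
            d[..., a], h[..., a, b], h[..., a, c],
            d[..., b], h[..., b, c], d[..., c],
        )
    e4 = det4_batch(h).real
    return np.stack([e1, e2, e3, e4], axis=-1)


# ---------------------------------------------------------------------------
# Cholesky pivots
# ---------------------------------------------------------------------------

def cholesky_pivots_batch(h: np.ndarray):
    """Pre-square-root pivots of the Cholesky elimination of each matrix.

    Runs the outer-product elimination H = L L*; ``pivots[k]`` is the value
    on the diagonal at step k *before* its square root is taken.  Once a
    pivot is <= 0 the remaining pivots are computed with a guarded divisor
    and are meaningless; callers must use ``first_nonpositive`` to truncate.

    Returns
    -------
    pivots : float64 array (..., 4)
    """
    a = np.array(h, dtype=np.complex128, copy=True)
    n = a.shape[:-2]
    pivots = np.empty(n + (4,), dtype=np.float64)
    for k in range(4):
        dk = a[..., k, k].real
        pivots[..., k] = dk
        if k < 3:
            safe = np.where(dk > 0, dk, 1.0)
            col = a[..., k + 1:, k]
            a[..., k + 1:, k + 1:] -= (
                col[..., :, None] * np.conj(col)[..., None, :]
            ) / safe[..., None, None]
    return pivots


# ---------------------------------------------------------------------------
# Pauli-trace power sums (the closed forms)
# ---------------------------------------------------------------------------

def trace_powers_batch(m: np.ndarray, return_intermediates: bool = False):
    """Power sums p_k = trace(H^k), k = 1..4, directly from Mueller elements.

    The closed forms below were derived from the Pauli expansion of H and
    verified exactly, in rational arithmetic, against trace(H^k) computed by
    explicit matrix powers (a regression test re-checks them numerically).
    No coherency matrix is formed.

    Returns ``p`` of shape (..., 4); with ``return_intermediates=True`` also
    a dict of the named intermediate quantities.
    """
    m = np.asarray(m, dtype=np.float64)
    m00 = m[..., 0, 0]
    q = np.einsum("...ij,...ij->...", m, m)          # sum of all 16 squares
    row0 = m[..., 0, 1:]
    col0 = m[..., 1:, 0]
    mt = m[..., 1:, 1:]
    d_ = np.einsum("...j,...j->...", row0, row0)      # D = sum m0i^2
    f_ = np.einsum("...i,...i->...", col0, col0)      # F = sum mi0^2
    s = np.einsum("...ij,...ij->...i", mt, mt)        # S1..S3 (rows of Mt)
    ss = s.sum(axis=-1)
    det_mt = det3_batch(mt)
    det_m = det4_batch(m)
    g = np.einsum("...i,...j,...ij->...", col0, row0, mt)
    a_ = np.einsum("...i,...i->...", s, s)
    b_ = np.einsum("...i,...i->...", col0 ** 2, ss[..., None] - s)
    # P_0j = m00*mj0 + sum_k m0k mjk ;  P_ij (i>=1) = mi0*mj0 - sum_k mik mjk
    p0 = m00[..., None] * col0 + np.einsum("...k,...jk->...j", row0, mt)
    gram = np.einsum("...ik,...jk->...ij", mt, mt)
    c_ = -np.einsum("...j,...j->...", p0, p0)
    for i in range(3):
        for j in range(i + 1, 3):
            pij = col0[..., i] * col0[..., j] - gram[..., i, j]
            c_ = c_ + pij ** 2
    k_ = np.einsum("...i->...", col0 ** 4)

    p1 = m00
    p2 = 0.25 * q
    p3 = 0.1875 * m00 * q - 0.125 * m00 ** 3 + 0.375 * (det_mt + g)
    p4 = (
        (3.0 / 64.0) * q ** 2
        - 0.125 * det_m
        - (1.0 / 32.0) * a_
        - (1.0 / 16.0) * b_
        - (1.0 / 16.0) * c_
        - (1.0 / 32.0) * (m00 ** 4 + k_)
        - (1.0 / 16.0) * m00 ** 2 * f_
        - (1.0 / 32.0) * d_ ** 2
        - (1.0 / 16.0) * d_ * ss
        + 0.5 * m00 * det_mt
        + 0.25 * m00 * g
    )
    p = np.stack([p1, p2, p3, p4], axis=-1)
    if not return_intermediates:
        return p
    inter = {
        "S1": s[..., 0], "S2": s[..., 1], "S3": s[..., 2],
        "A": a_, "B": b_,
        "P01": p0[..., 0], "P02": p0[..., 1], "P03": p0[..., 2],
        "P12": col0[..., 0] * col0[..., 1] - gram[..., 0, 1],
        "P13": col0[..., 0] * col0[..., 2] - gram[..., 0, 2],
        "P23": col0[..., 1] * col0[..., 2] - gram[..., 1, 2],
        "C": c_, "D": d_, "F": f_,
        "det_M": det_m, "det_Mtilde": det_mt,
    }
    return p, inter


def newton_cp_from_powers(p: np.ndarray) -> np.ndarray:
    """Elementary symmetric e1..e4 from power sums p1..p4 (Newton identities)."""
    p1, p2, p3, p4 = (p[..., k] for k in range(4))
    e1 = p1
    e2 = (p1 ** 2 - p2) / 2.0
    e3 = (p1 ** 3 - 3.0 * p1 * p2 + 2.0 * p3) / 6.0
    e4 = (p1 ** 4 - 6.0 * p1 ** 2 * p2 + 3.0 * p2 ** 2
          + 8.0 * p1 * p3 - 6.0 * p4) / 24.0
    return np.stack([e1, e2, e3, e4], axis=-1)


# ---------------------------------------------------------------------------
# batched classification
# ---------------------------------------------------------------------------

def _tau(tol, scale: np.ndarray, degree: int = 1) -> np.ndarray:
    """Effective threshold max(abs_tol, rel_tol * |scale|^degree)."""
    return np.maximum(tol.abs_tol, tol.rel_tol * np.abs(scale) ** degree)


def classify_batch(m: np.ndarray, method: str, tol, criterion: str | None = None):
    """Classify a stack of Mueller matrices with one realizability test.

    Parameters
    ----------
    m : float64 array (..., 4, 4)
    method : one of METHODS
    tol : Tolerance
    criterion : 'semidefinite', 'strictly_definite', or None for the
        method default.  Cholesky and Sylvester only support strict.

    Returns
    -------
    physical : bool array (...)
    witness : float64 array (...) -- the deciding quantity per matrix
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid methods: {METHODS}")
    if criterion is None:
        criterion = DEFAULT_CRITERION[method]
    if criterion not in ("semidefinite", "strictly_definite"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if method in ("chol", "sylvester") and criterion == "semidefinite":
        raise ValueError(
            f"method {method!r} only tests strict positive definiteness"
        )
    m = np.asarray(m, dtype=np.float64)
    trace_scale = m[..., 0, 0]

    if method == "cp_pauli":
        p = trace_powers_batch(m)
        e = newton_cp_from_powers(p)
        return _classify_cp(e, tol, trace_scale, criterion)

    h = coherency_from_mueller(m)
    if method == "eig":
        lam = np.linalg.eigvalsh(h)
        lmin = lam[..., 0]
        tau = _tau(tol, trace_scale)
        if criterion == "semidefinite":
            return lmin >= -tau, lmin
        return lmin > tau, lmin
    if method == "chol":
        pivots = cholesky_pivots_batch(h)
        tau = _tau(tol, trace_scale)
        ok = pivots > tau[..., None]
        physical = ok.all(axis=-1)
        first_bad = np.argmin(ok, axis=-1)          # 0 if all ok; masked below
        witness = np.where(
            physical,
            np.min(pivots, axis=-1),
            np.take_along_axis(pivots, first_bad[..., None], axis=-1)[..., 0],
        )
        return physical, witness
    if method == "sylvester":
        minors = sylvester_minors_batch(h)
        degs = np.arange(1, 5)
        tau_k = np.maximum(
            tol.abs_tol,
            tol.rel_tol * np.abs(trace_scale)[..., None] ** degs,
        )
        ok = minors > tau_k
        physical = ok.all(axis=-1)
        first_bad = np.argmin(ok, axis=-1)
        witness = np.where(
            physical,
            np.min(minors, axis=-1),
            np.take_along_axis(minors, first_bad[..., None], axis=-1)[..., 0],
        )
        return physical, witness
    # cp_direct
    e = cp_coefficients_batch(h)
    return _classify_cp(e, tol, trace_scale, criterion)


def _classify_cp(e: np.ndarray, tol, trace_scale: np.ndarray, criterion: str):
    degs = np.arange(1, 5)
    tau_k = np.maximum(
        tol.abs_tol, tol.rel_tol * np.abs(trace_scale)[..., None] ** degs
    )
    margin = e + tau_k if criterion == "semidefinite" else e - tau_k
    if criterion == "semidefinite":
        ok = e >= -tau_k
    else:
        ok = e > tau_k
    physical = ok.all(axis=-1)
    worst = np.argmin(margin, axis=-1)
    witness = np.take_along_axis(e, worst[..., None], axis=-1)[..., 0]
    return physical, witness
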