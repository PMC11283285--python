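"""The five positive-(semi)definiteness tests and their closed forms."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from muellercheck import (
    Tolerance,
    check_cholesky,
    check_cp,
    check_eigenvalues,
    check_sylvester,
    coherency_from_mueller,
    cp_coefficients_direct,
    cp_from_traces,
    mueller_from_coherency,
    sylvester_minors,
    trace_powers_pauli,
)
from muellercheck import _kernels

from conftest import random_gram_psd, random_hermitian

TOL = Tolerance()


def h_of(m):
    return coherency_from_mueller(np.asarray(m, dtype=float))


class TestEigenvalues:
    def test_identity_physical_under_both_criteria(self):
        for criterion in ("semidefinite", "strictly_definite"):
            v, lam = check_eigenvalues(np.eye(4, dtype=complex), TOL, criterion)
            assert v.physical and v.witness == pytest.approx(1.0)
            assert np.allclose(lam, [1, 1, 1, 1])

    def test_small_negative_eigenvalue_flagged(self):
        v, _ = check_eigenvalues(np.diag([1.0, 1, 1, -0.01]).astype(complex), TOL)
        assert not v.physical
        assert v.witness == pytest.approx(-0.01)

    def test_singular_psd_semidefinite_but_not_strict(self):
        h = h_of(np.eye(4))  # rank-1, eigenvalues (1, 0, 0, 0)
        v_semi, lam = check_eigenvalues(h, TOL, "semidefinite")
        v_strict, _ = check_eigenvalues(h, TOL, "strictly_definite")
        assert v_semi.physical and not v_strict.physical
        assert np.allclose(lam, [1, 0, 0, 0], atol=1e-12)

    def test_spectrum_sums_to_trace(self, rng):
        h = random_hermitian(rng, 200)
        for hh in h[:20]:
            _, lam = check_eigenvalues(hh, TOL)
            tr = hh.trace().real
            assert abs(lam.sum() - tr) <= 1e-9 * abs(tr) + 1e-12


class TestCholesky:
    def test_diagonal_case_pivots(self):
        v, res = check_cholesky(np.diag([1.0, 2, 3, 4]).astype(complex), TOL)
        assert v.physical and res.success
        assert res.pivots == pytest.approx((1, np.sqrt(2), np.sqrt(3), 2))

    def test_indefinite_fails_at_last_pivot(self):
        v, res = check_cholesky(np.diag([1.0, 1, 1, -1]).astype(complex), TOL)
        assert not v.physical and res.failure_index == 3
        assert v.witness == pytest.approx(-1.0)

    def test_singular_psd_rejected_by_strict_test(self):
        # Cholesky decides definiteness only: rank-1 PSD has a zero pivot
        v, res = check_cholesky(h_of(np.eye(4)), TOL)
        assert not v.physical and not res.success

    def test_matches_numpy_cholesky_on_pd_matrices(self, rng):
        for hh in random_gram_psd(rng, 50):
            v, res = check_cholesky(hh, TOL)
            if v.physical:
                ell = np.linalg.cholesky(hh)
                assert np.allclose(res.pivots, np.diag(ell).real, atol=1e-10)


class TestSylvester:
    def test_minor_examples(self):
        assert sylvester_minors(np.diag([1.0, 2, 3, 4]).astype(complex)) == (
            pytest.approx([1, 2, 6, 24])
        )
        assert sylvester_minors(np.diag([-1.0, 1, 1, 1]).astype(complex))[0] == -1
        h = np.eye(4, dtype=complex)
        h[0, 1], h[1, 0] = 1j, -1j
        assert sylvester_minors(h)[1] == pytest.approx(0.0, abs=1e-14)

    def test_minors_match_generic_determinant_oracle(self, rng):
        """Regression pin of the committed closed forms to numpy's det."""
        h = random_hermitian(rng, 300)
        minors = _kernels.sylvester_minors_batch(h)
        for k in range(1, 5):
            oracle = np.linalg.det(h[:, :k, :k]).real
            assert np.allclose(minors[:, k - 1], oracle, atol=1e-10)

    def test_verdict_examples(self):
        assert check_sylvester(np.diag([1.0, 2, 3, 4]).astype(complex), TOL).physical
        v = check_sylvester(np.diag([1.0, 1, 1, -1]).astype(complex), TOL)
        assert not v.physical and v.witness == pytest.approx(-1.0)
        # H of diag(1,1,1,-1) has eigenvalues {1/2, 1/2, 1/2, -1/2}
        assert not check_sylvester(h_of(np.diag([1.0, 1, 1, -1])), TOL).physical


class TestCPDirect:
    def test_examples(self):
        assert cp_coefficients_direct(
            np.diag([1.0, 2, 3, 4]).astype(complex)
        ) == pytest.approx([10, 35, 50, 24])
        assert cp_coefficients_direct(np.zeros((4, 4), complex)) == pytest.approx(
            [0, 0, 0, 0]
        )
        assert cp_coefficients_direct(h_of(np.eye(4))) == pytest.approx(
            [1, 0, 0, 0], abs=1e-12
        )

    def test_matches_elementary_symmetric_of_eigenvalues(self, rng):
        h = random_hermitian(rng, 300)
        e = _kernels.cp_coefficients_batch(h)
        lam = np.linalg.eigvalsh(h)
        for k in range(1, 5):
            oracle = np.zeros(len(h))
            for comb in itertools.combinations(range(4), k):
                oracle += np.prod(lam[:, comb], axis=1)
            scale = np.maximum(np.abs(oracle), 1.0)
            assert np.all(np.abs(e[:, k - 1] - oracle) <= 1e-9 * scale)


class TestTracePowers:
    def test_ideal_depolarizer(self):
        p = trace_powers_pauli(np.diag([1.0, 0, 0, 0]))
        assert p == pytest.approx([1, 0.25, 1 / 16, 1 / 64])

    def test_identity_mueller(self):
        assert trace_powers_pauli(np.eye(4)) == pytest.approx([1, 1, 1, 1])

    def test_against_explicit_matrix_powers(self, rng):
        m = rng.normal(size=(1000, 4, 4))
        p = _kernels.trace_powers_batch(m)
        h = coherency_from_mueller(m)
        hk = h.copy()
        for k in range(4):
            tr = np.einsum("nii->n", hk).real
            assert np.abs(p[:, k] - tr).max() < 1e-10
            hk = hk @ h

    @pytest.mark.filterwarnings("ignore::DeprecationWarning")
    def test_exact_symbolic_oracle_pins_frozen_constants(self, rng):
        """Every constant in the closed forms, re-checked in exact arithmetic.

        sympy evaluates trace(H^k) for integer Mueller matrices with exact
        rational/complex entries -- a path fully independent of the
        floating-point closed forms.
        """
        import sympy as sp

        sigma = [
            sp.eye(2),
            sp.Matrix([[1, 0], [0, -1]]),
            sp.Matrix([[0, 1], [1, 0]]),
            sp.Matrix([[0, -sp.I], [sp.I, 0]]),
        ]
        basis = [
            [sp.Matrix(sp.kronecker_product(sigma[i], sigma[j].T)) for j in range(4)]
            for i in range(4)
        ]
        for _ in range(5):
            mi = rng.integers(-5, 6, size=(4, 4))
            h = sp.zeros(4, 4)
            for i in range(4):
                for j in range(4):
                    h += int(mi[i, j]) * basis[i][j]
            h = h / 4
            p = _kernels.trace_powers_batch(mi.astype(float)[None])[0]
            hk = sp.eye(4)
            for k in range(4):
                hk = hk * h
                exact = float(sp.simplify(hk.trace()))
                assert p[k] == pytest.approx(exact, rel=1e-12, abs=1e-12)

    def test_even_powers_nonnegative(self, rng):
        p = _kernels.trace_powers_batch(rng.normal(size=(2000, 4, 4)))
        assert np.all(p[:, 1] >= 0)
        assert np.all(p[:, 3] >= -1e-15)

    def test_intermediates_sign_invariants(self, rng):
        for m in rng.normal(size=(30, 4, 4)):
            p, inter = trace_powers_pauli(m, return_intermediates=True)
            assert inter["A"] >= 0 and inter["B"] >= 0
            assert inter["D"] >= 0 and inter["F"] >= 0
            assert p[0] == m[0, 0]


class TestNewtonIdentities:
    @pytest.mark.parametrize(
        "p, e",
        [
            ((10, 30, 100, 354), (10, 35, 50, 24)),
            ((0, 0, 0, 0), (0, 0, 0, 0)),
            ((1, 1, 1, 1), (1, 0, 0, 0)),
        ],
    )
    def test_frozen_examples(self, p, e):
        assert cp_from_traces(np.asarray(p, float)) == pytest.approx(e)

    def test_exact_on_integer_eigenvalues(self, rng):
        """Rational arithmetic: power sums -> elementary symmetric, exactly."""
        for _ in range(50):
            lam = [Fraction(int(x)) for x in rng.integers(-9, 10, size=4)]
            p = [sum(v**k for v in lam) for k in range(1, 5)]
            e = cp_from_traces(p)
            for k in range(1, 5):
                expected = sum(
                    Fraction(np.prod([int(c.numerator) for c in comb]))
                    for comb in itertools.combinations(lam, k)
                )
                assert e[k - 1] == expected


class TestCheckCP:
    @pytest.mark.parametrize("variant", ["direct", "pauli"])
    def test_examples(self, variant):
        assert check_cp(np.eye(4), variant, TOL).physical
        assert not check_cp(np.diag([1.0, 1, 1, -1]), variant, TOL).physical
        assert check_cp(np.diag([1.0, 0.5, 0.5, 0.25]), variant, TOL).physical
        assert not check_cp(np.diag([1.0, 0.6, 0.6, 0.1]), variant, TOL).physical

    def test_indefinite_witness_is_negative_coefficient(self):
        v = check_cp(np.diag([1.0, 1, 1, -1]), "pauli", TOL)
        # eigenvalues {1/2,1/2,1/2,-1/2}: e3 = -1/4 and e4 = -1/16 are both
        # negative; the witness is the most violating one
        assert v.witness == pytest.approx(-1 / 4)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            check_cp(np.eye(4), "maple", TOL)


class TestCrossMethodAgreement:
    def test_verdicts_agree_away_from_boundary(self, rng):
        """eig, cp_direct, cp_pauli identical; chol/sylvester consistent."""
        h = np.concatenate(
            [random_hermitian(rng, 1500), random_gram_psd(rng, 500)]
        )
        m = mueller_from_coherency(h)
        lam = np.linalg.eigvalsh(h)[:, 0]
        tau = np.maximum(TOL.abs_tol, TOL.rel_tol * np.abs(m[:, 0, 0]))
        clear = np.abs(lam) > 10 * tau
        verdicts = {
            meth: _kernels.classify_batch(m, meth, TOL)[0]
            for meth in ("eig", "cp_direct", "cp_pauli")
        }
        assert np.array_equal(verdicts["eig"][clear], verdicts["cp_direct"][clear])
        assert np.array_equal(verdicts["eig"][clear], verdicts["cp_pauli"][clear])
        strict_clear = (lam > 10 * tau) | (lam < -10 * tau)
        for meth in ("chol", "sylvester"):
            ok = _kernels.classify_batch(m, meth, TOL)[0]
            assert np.array_equal(ok[strict_clear], verdicts["eig"][strict_clear])

    def test_descartes_criterion_sound(self, rng):
        """All CP coefficients nonnegative <=> smallest eigenvalue nonnegative."""
        h = random_hermitian(rng, 5000)
        e = _kernels.cp_coefficients_batch(h)
        lam = np.linalg.eigvalsh(h)[:, 0]
        clear = np.abs(lam) > 1e-8
        assert np.array_equal(
            np.all(e[clear] >= -1e-10, axis=1), lam[clear] >= 0
        )

    def test_scale_invariance_of_verdicts(self, rng):
        h = np.concatenate(
            [random_hermitian(rng, 200), random_gram_psd(rng, 100)]
        )
        m = mueller_from_coherency(h)
        for meth in _kernels.METHODS:
            base = _kernels.classify_batch(m, meth, TOL)[0]
            for alpha in (0.5, 2.0):
                assert np.array_equal(
                    _kernels.classify_batch(alpha * m, meth, TOL)[0], base
                )

    def test_chol_semidefinite_criterion_rejected(self):
        with pytest.raises(ValueError, match="strict"):
            _kernels.classify_batch(
                np.eye(4)[None], "chol", TOL, "semidefinite"
            )
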