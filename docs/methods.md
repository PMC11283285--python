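# Methods

## The realizability criterion

A Mueller matrix M is the 4×4 real transfer matrix of a sample acting on
Stokes vectors.  Its Hermitian coherency matrix is the Pauli-basis
expansion

    H = (1/4) Σ_{i,j=0..3} m_ij (σ_i ⊗ σ_jᵀ),

with σ₀ = I₂, σ₁ = diag(1, −1), σ₂ = [[0,1],[1,0]], σ₃ = [[0,−i],[i,0]].
The basis matrices B_ij = σ_i ⊗ σ_jᵀ are Hermitian and trace-orthogonal
(tr B_ij B_kl = 4 δ_ik δ_jl), which makes the expansion exactly invertible:
m_ij = tr(H B_ij).  M is physically realizable — maps every valid Stokes
vector to a valid one — iff H ⪰ 0.  The Pauli ordering and signs above are
fixed; every closed form below depends on that convention, and the basis
properties are asserted exactly (the entries are 0, ±1, ±i) in the tests.

## The five decision algorithms

* **Eigenvalues** (`eig`): λ_min(H) ≥ −τ (semidefinite) or > τ (strict).
  Slowest but yields the spectrum, which downstream eigenvalue-based
  depolarization metrics reuse; it is returned alongside the verdict.
* **Cholesky** (`chol`): the elimination H = LL\* succeeds with every
  pre-square-root pivot > τ.  Decides *strict* definiteness only — a
  singular PSD matrix (e.g. the coherency matrix of an ideal non-depolarizing
  element) is reported nonphysical.  Acceptable for tissue imaging, where
  strong depolarization makes H strictly definite.
* **Sylvester** (`sylvester`): all four leading principal minors Δ_k > τ_k.
  Also strict-only.  The minors are committed closed-form expansions in the
  entries of H (2×2 and Hermitian-3×3 formulas, cofactor expansion for the
  4×4); no generic determinant routine runs per pixel.
* **CP coefficients, direct** (`cp_direct`): with real eigenvalues,
  H ⪰ 0 ⟺ all coefficients of f(λ) = det(H + λI) are nonnegative
  (Descartes' rule of signs; the "+" sign makes the coefficients the
  elementary symmetric polynomials e₁..e₄ of the eigenvalues).  e₁ is the
  trace, e₂/e₃ sums of 2×2/3×3 principal minors, e₄ the determinant, all as
  committed expansions.
* **CP coefficients via Pauli traces** (`cp_pauli`): the power sums
  p_k = tr Hᵏ are evaluated in closed form directly on the Mueller
  elements — H is never constructed — then converted to e₁..e₄ with
  Newton's identities
  e₁ = p₁, e₂ = (p₁² − p₂)/2, e₃ = (p₁³ − 3p₁p₂ + 2p₃)/6,
  e₄ = (p₁⁴ − 6p₁²p₂ + 3p₂² + 8p₁p₃ − 6p₄)/24.

## The frozen trace formulas

With Q = Σ m_ij² (all 16 elements), M̃ the lower-right 3×3 block,
S_i = Σ_j m_ij² (rows of M̃), S = S₁+S₂+S₃, D = Σ m₀ⱼ², F = Σ mᵢ₀²,
G = Σ_{i,j≥1} m_i0 m_0j m_ij, A = Σ S_i²,
B = m₁₀²(S₂+S₃) + m₂₀²(S₁+S₃) + m₃₀²(S₁+S₂),
P₀ⱼ = m₀₀ m_j0 + Σ_k m₀ₖ m_jk,  P_ij = m_i0 m_j0 − Σ_k m_ik m_jk (i ≥ 1),
C = −P₀₁² − P₀₂² − P₀₃² + P₁₂² + P₁₃² + P₂₃²,
K = m₁₀⁴ + m₂₀⁴ + m₃₀⁴:

    p₁ = m₀₀
    p₂ = Q/4
    p₃ = (3/16) m₀₀ Q − m₀₀³/8 + (3/8)(det M̃ + G)
    p₄ = (3/64) Q² − det M / 8 − A/32 − B/16 − C/16
         − (m₀₀⁴ + K)/32 − m₀₀² F/16 − D²/32 − D·S/16
         + m₀₀ det M̃ / 2 + m₀₀ G / 4

These constants were derived by an exact rational-arithmetic fit of
tr(Hᵏ) — computed symbolically from the Pauli expansion — against the
candidate polynomial basis, and verified exactly on independent random
integer matrices before being frozen.  Typeset versions of such formulas in
the literature are easy to corrupt (a factor in p₂ and a sign in p₃ are
commonly garbled), so the package treats the numeric/symbolic oracle as the
sole authority: a regression test re-verifies all four formulas against
explicit matrix powers of H on 1000 random matrices (≤ 1e−10 absolute at
unit scale) and against an exact sympy evaluation on integer matrices.

## Tolerances and criteria

The mathematical decision "is x positive?" needs a floating-point threshold.
A `Tolerance(abs_tol=1e−12, rel_tol=1e−9)` gives the effective threshold
for a quantity of polynomial degree k in H as

    τ_k = max(abs_tol, rel_tol · |tr H|ᵏ).

Degree scaling (minors and CP coefficients of degree k scale as the k-th
power of the intensity) makes every verdict invariant under rescaling
M → αM, so m₀₀-normalized and raw data produce identical masks; this is
property-tested.  Defaults suit unit-scale (m₀₀-normalized) data; abs_tol
is a floor for matrices with vanishing trace.

Criteria: `eig`, `cp_direct`, `cp_pauli` default to *semidefinite*
(physical iff witness ≥ −τ; ties at |witness| ≤ τ count as physical, so
rounding never discards boundary pixels), matching the exact realizability
condition.  `chol` and `sylvester` can only certify *strict* definiteness
and default to it; requesting a semidefinite verdict from them is an error
rather than a silent reinterpretation.

Methods may legitimately disagree within ~10τ of the PSD boundary (and
strict vs semidefinite tests disagree exactly on singular PSD pixels);
`compare_methods` therefore splits disagreements into boundary
(|λ_min| ≤ 10τ) and non-boundary sets, and only the latter indicates a
defect.

## Pixel-wise filtering and parallelism

Images are (rows, cols, 4, 4) float64 arrays.  Classification is vectorized
over pixels and chunked by blocks of whole rows; each chunk writes a
disjoint slice of the output mask, so the result is bit-identical for every
`workers`/`chunk_rows` combination (asserted at full scale).  Threads are
used rather than processes: the kernels are numpy-bound and release the
GIL.  Non-finite pixels are flagged at ingest and either counted as
nonphysical (default — the filter's purpose is discarding unusable pixels)
or excluded from the denominator; they are reported separately either way.

The benchmark harness reports wall-clock mean ± sd per (method, workers)
cell.  Timings are hardware- and BLAS-dependent observations; the package
logs the observed ranking (typically `cp_pauli` fastest, `eig` slowest,
since the eigensolver computes spectra the filter never uses) but asserts
nothing about it.

## Synthetic data

The generator emulates m₀₀-normalized Mueller images of depolarizing
tissue:

* *Physical pixels*: H = GG\* with G a complex 4×rank standard-normal
  factor, trace-normalized to 1 (so m₀₀ = 1), mapped back through the basis
  inversion.  Rank 4 (generic depolarizing medium) is the default; Gram
  construction makes PSD exact by construction.
* *Planted nonphysical pixels*: a rank-one negative perturbation
  H − (λ_min + δ) vv\* along the smallest-eigenvalue direction, δ uniform
  in [10⁻³, 10⁻²] of the trace — a controllable violation depth comparable
  to the percent-level element errors of real instruments — then
  trace-renormalized.  The planted set has exactly
  round(frac_nonphysical · rows · cols) members, chosen by a seeded draw.
* *Noise*: optional i.i.d. Gaussian noise per element (sd = noise_sigma ·
  m₀₀), mimicking residual random measurement error (real systems achieve
  below 1%).
* *Margin enforcement*: after noise, every pixel is rejection-sampled until
  its coherency λ_min clears ±10τ of zero on its labeled side, so the truth
  mask is exact and every boundary-respecting test must reproduce it.

Randomness comes from per-row Philox streams keyed on (seed, row), pixels
drawn in column order: generated data depend only on the seed and pixel
position, never on chunking or worker count.

What passing on this generator does *not* show: real polarimetric errors
are spatially correlated, element-dependent and partly systematic
(calibration residuals), and real nonphysical pixels cluster near the PSD
boundary instead of being margin-separated.  The generator validates the
algebra and the filtering machinery, not instrument error models; on real
data, boundary pixels may flip between methods within tolerance, which is
why `compare_methods` reports the boundary set explicitly.

## Problem sizes and numerical choices

The validation suite runs at the scale of one full camera frame: 600×700 =
420 000 pixels with a planted nonphysical fraction of 0.002 (840 pixels),
1000 random matrices for the trace-formula pin, 10 000 Hermitian matrices
for cross-method agreement, and a 1001-point scan of the diag(1, a, a, b)
family, whose coherency spectrum is the closed form
{(1+2a+b)/4, (1−2a+b)/4, (1−b)/4, (1−b)/4} and whose realizability
boundary is the line 1 − 2a + b = 0.

Degenerate inputs: empty images and non-4×4 arrays are rejected; non-finite
elements are rejected in single-matrix calls (naming the element) and
masked in images; a non-Hermitian input to the basis inversion is rejected
beyond 1e−10 absolute.  The Cholesky elimination guards its divisor after a
failed pivot; pivots past the first failure are not reported.

## Known limitations

* `chol`/`sylvester` cannot certify semidefiniteness; exactly-singular PSD
  matrices are flagged nonphysical by them (by design, documented above).
* Sylvester's Δ₄ compares the full determinant (degree 4) against τ₄; for
  strictly definite matrices with λ_min barely above 10τ the determinant
  can still fall below τ₄, so near-singular but definite pixels may be
  conservatively flagged — another reason the semidefinite CP/eigenvalue
  tests are the default filter.
* No repair/projection of nonphysical matrices onto the PSD cone, no
  Mueller decompositions, no exploitation of temporal coherence between
  video frames.
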