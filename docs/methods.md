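# Methods

## The problem

Motor-imagery brain–computer interfaces classify which movement a
subject *imagines* from multichannel EEG. Imagery suppresses the power
of the mu (8–13 Hz) and beta (14–30 Hz) rhythms over the contralateral
motor cortex (event-related desynchronization, ERD), so the signal of
interest is a *joint* spatial–spectral pattern: which channels lose
band power, and in which frequency band. This package implements a
feature-extraction stack that preserves both axes end to end.

## Pipeline overview

1. **Filter bank.** Nine contiguous 4 Hz bandpass filters covering
   4–40 Hz, 6th-order Chebyshev type II with 40 dB stopband attenuation,
   applied zero-phase (forward–backward) by default.
2. **OVR-FBCSP.** In each band, one-versus-rest common spatial patterns:
   for each class `c`, solve `C_c w = λ (C_c + C_rest) w` on
   trace-normalized average trial covariances and keep the `m` filters
   from each end of the spectrum. Per trial this yields an
   `N_f × N_g` feature matrix `X` (`N_f = 9` bands,
   `N_g = 2·m·Z` log-normalized-variance CSP features), rows indexing
   frequency, columns indexing spatial filters.
3. **Projection.** One of: none (raw vectorized matrix), LDA, 2DLDA,
   DLPP, 2DDLPP, or the bilinear 2DDLPP below.
4. **Classifier.** Linear-kernel SVM, C = 1, after per-feature
   standardization fit on the training split.
5. **Protocol.** Stratified 5-fold cross-validation on the training set
   jointly selects `m ∈ {1..4}` and the feature dimension `d_op`; the
   test set is scored once by the pipeline refit on all training data at
   `(m, d_op)`.

## The bilinear discriminant projection

Each class of feature matrices is modelled as matrix-variate Gaussian:
under column-major vectorization,

    vec(X) ~ N(vec(M_c), ψ ⊗ φ),

with `φ` (`N_f × N_f`) the spectral (row) covariance and `ψ`
(`N_g × N_g`) the spatial (column) covariance. The Kronecker
separability is what lets the within-class structure be estimated and
inverted per side instead of on the full `N_f·N_g`-dimensional
vectorization.

The within-class factors are heat-kernel-weighted pair scatters over
all same-class pairs (`W_ij = exp(-‖X_i - X_j‖²_F / t)`, `t = 1`):

    ψ = 1/(2 N_f) Σ_s Σ_ij W_ij^s (X_i − X_j)ᵀ (X_i − X_j)
    φ = 1/(2 N_g) Σ_s Σ_ij W_ij^s (X_i − X_j) (X_i − X_j)ᵀ

and the between-class scatter over class means `F_a` splits into a left
and a right factor, the right one carrying `1/tr(S_BL)` so the
Kronecker product of the two keeps the overall scale:

    S_BL = ½ Σ_ab B_ab (F_a − F_b)(F_a − F_b)ᵀ
    S_BR = tr⁻¹(S_BL) · ½ Σ_ab B_ab (F_a − F_b)ᵀ(F_a − F_b)

with `B_ab = exp(-‖F_a − F_b‖²_F / t)`. Maximizing between- over
within-class spread separately per side gives two small generalized
eigenproblems,

    S_BL u = λ φ u    and    S_BR v = γ ψ v,

both spectra sorted descending. The transform is `Y = Uᵀ X V`, and the
`d` retained features are the entries `y_lj` with the largest products
`λ_l · γ_j` — a feature is kept only if it is discriminative on *both*
the spectral and the spatial side. The eigenvalue-product ranking is
invariant to any per-side rescaling of `φ` or `ψ`, which is why the
fixed `1/(2N_f)`, `1/(2N_g)` estimator scalings (rather than the
mutually trace-coupled definitions of the abstract model) are harmless.

A useful consequence of the column-major convention:
`vec(Uᵀ X V) = (V ⊗ U)ᵀ vec(X)` exactly, which the test suite uses to
pin the vectorization order.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| bands | nine 4 Hz bands, 4–40 Hz | span mu and beta rhythms |
| filter order | 6 (even) | Chebyshev-II bandpass, flat delay |
| stopband attenuation | 40 dB | common Chebyshev-II working point |
| zero_phase | True | forward–backward filtering; no group delay |
| m | grid 1..4 | CSP filter pairs per class; `2m ≤ n_channels` |
| t | 1.0 | heat-kernel width on squared Frobenius distance |
| ridge | 1e-6 × trace/dim | on `φ`, `ψ` and singular denominators |
| CSP ridge | 1e-8 × trace/dim | on rank-deficient composite covariance |
| SVM | linear, C = 1 | standard for CSP log-variance features |
| n_folds | 5 | stratified; class counts per fold within ±1 |

`d_grid="auto"` expands to a ≤40-point geometric grid over
`1..N_f·N_g` for vector and bilinear methods and to `1..N_f` for the
one-sided matrix methods, matching the very different dimensionality
ranges of the two families.

## Synthetic data: what it emulates, what it does not

`generate_dataset` draws trials as

    x(t) = Σ_k a_k(class) · p_k · s_k(t) + noise,

where each `s_k` is unit-variance band-limited noise (white noise
through the same Chebyshev-II design as the analysis bank, so spectral
content matches the analysis bands), `p_k` is a fixed unit-norm spatial
pattern (smooth bumps over staggered channel groups), and class `c`
attenuates its associated source by `1 − erd_depth`. ERD is encoded
purely as amplitude attenuation because CSP and everything downstream
is variance-driven. The default benchmark — 2 classes, 8 channels,
250 Hz, 3 s trials, 60 trials/class, two mu-band sources, erd_depth
0.7, source amplitude 2.0, broadband noise SD 1.0 — is an easy
(Bayes ≈ 1) regime sized to run the full cross-validation pipeline in
seconds; `null_config` (erd_depth 0) removes all class structure for
chance-level controls.

Deliberately *not* modelled: volume conduction and realistic head
geometry, ERD time courses within a trial, artifacts (EOG/EMG), 1/f
background spectra, or inter-subject variability. Passing tests on this
generator therefore demonstrate correctness of the algorithms and
recoverability of planted spatial–spectral structure — not performance
on real EEG.

`generate_matrix_gaussian_set` samples `X = M_c + L_φ E L_ψᵀ` (Cholesky
factors, iid normal `E`), the exact matrix-variate model above; it is
the testbed for covariance-separability recovery and for planting
rank-1 between-class structure at a known (row, column) support.

## Numerical choices

- All generalized eigenproblems are solved in symmetric-definite form
  (`scipy.linalg.eigh` on the pencil) rather than by forming `φ⁻¹S_BL`;
  residuals `‖S v − λ T v‖` are checked after every solve (tolerance
  1e-8, scale-normalized). An independent QZ solve is the test oracle.
- Denominators that fail Cholesky get a ridge `ε·trace/dim·I`
  (`ε = 1e-6`; logged). `φ` and `ψ` are ridge-regularized before the
  bilinear solves — FBCSP feature counts can exceed per-class sample
  counts.
- Graph Laplacians are assembled from the off-diagonal weights only.
  `L = D − W` cancels the unit self-weight exactly, and forming
  `1 + ε − 1` in floating point destroys off-diagonal weights below
  machine epsilon (pairs of distant class means reach `W ~ 1e-20`).
- If *every* between-class weight would underflow (`d²/t > 500`), the
  minimum squared distance is factored out of the off-diagonal weights
  before exponentiating. This rescales `S_BL` and `λ` by a constant and
  leaves eigenvectors, `S_BR`, `γ` and the `λ·γ` ranking unchanged; the
  factored-out log-constant is recorded on the graph object.
- Determinism: eigenvector signs are fixed (largest-magnitude entry
  positive); equal `λ_l·γ_j` products tie-break lexicographically by
  ascending `(l, j)`; grid ties in cross-validation resolve toward
  smaller `d`, then smaller `m`; every random draw flows from one seed.
- Weights are computed over all within-class pairs (complete graph), as
  the defining sums state; a k-NN mask exists but is off by default.
- Degenerate inputs: identical class means raise a "no between-class
  structure" error; a class with fewer than two trials is rejected at
  validation; zero-variance projected signals are reported with the
  offending filter index.

## Open design points resolved

- The 2DDLPP/2DLDA projections are left-sided (`Y = AᵀX`, row/spectral
  compression), forced by the `N_f × N_f` dimensions of their scatter
  definitions; the exact dimensional collapse onto the vector methods
  (used as a test oracle) then occurs for single-column matrices.
- The CSP feature functional is log normalized variance (the standard
  filter-bank CSP convention; the source description names the method
  by citation only). It is scale-invariant per trial.
- Filtering direction is unstated in the protocol this follows;
  zero-phase is the default and a causal single pass is a config flag.
- CSP and the projection are refit inside every cross-validation fold
  (no leakage); the filter bank, being stateless, is applied once. An
  audit of fit/validation indices is recorded in every report, and a
  `fit-frontend-once` style shortcut is deliberately not offered.

## Problem sizes

The test suite and the acceptance script use the default benchmark
(120 trials × 8 channels × 750 samples) for end-to-end runs, 10
seeded replicates for the benchmark median, 20 seeds for
planted-structure recovery, 100 random sets for the conservation law,
and ≤10-sample sets of 3×4 matrices for the loop-oracle equation
checks; the whole suite completes in about a minute on one CPU.

## Known limitations

- The heat kernel with `t = 1` saturates when feature scales are large
  (weights underflow); the stabilization above keeps the between-class
  ranking intact, but within-class graphs can still become effectively
  unweighted for very spread-out classes.
- With fewer samples than `N_f·N_g`, the vector-method (LDA/DLPP)
  pencils are rank-deficient and their smallest eigenvalues are
  noise-dominated; the FBCSP front end is meant to keep the feature
  dimension below the sample count, and the library relies on that
  regime.
- Accuracies on the synthetic benchmark say nothing quantitative about
  competition or clinical EEG; reproducing published per-subject
  numbers requires the external recordings and their exact, partly
  unstated preprocessing conventions.
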