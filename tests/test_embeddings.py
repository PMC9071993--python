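import numpy as np
import pytest

from mifex import (
    LabeledMatrixSet,
    ValidationError,
    build_graph,
    fit_2ddlpp,
    fit_2dlda,
    fit_dlpp,
    fit_lda,
    heat_kernel_weights,
    transform,
    vectorize_matrix,
)
from mifex._linalg import eig_residuals
from mifex.embeddings import _row_scatters_dlpp

from .conftest import random_matrix_set
from . import oracles


class TestHeatKernel:
    def test_identical_items_weight_one(self):
        items = [np.ones((2, 2))] * 3
        np.testing.assert_allclose(heat_kernel_weights(items, t=1.0), 1.0)

    def test_distance_equal_t_gives_exp_minus_one(self):
        v1, v2 = np.zeros(3), np.array([np.sqrt(2.0), 0.0, 0.0])
        W = heat_kernel_weights([v1, v2], t=2.0)
        assert W[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        np.testing.assert_array_equal(np.diag(W), 1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        items = [rng.standard_normal((2, 2)) for _ in range(3)]
        W = heat_kernel_weights(items, t=1.3)
        np.testing.assert_allclose(W, oracles.heat_kernel_loop(items, 1.3), atol=1e-12)

    def test_nonpositive_t_rejected(self):
        with pytest.raises(ValidationError):
            heat_kernel_weights([np.zeros(2), np.ones(2)], t=0.0)


class TestBuildGraph:
    def test_two_identical_samples_laplacian(self):
        mats = np.stack([np.ones((2, 2))] * 2 + [np.zeros((2, 2))] * 2)
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1, 1, 2, 2]))
        g = build_graph(ms, t=1.0)
        np.testing.assert_allclose(g.L_s[0], [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)

    def test_identical_class_means_give_zero_row_sum_h(self):
        base = np.arange(4.0).reshape(2, 2)
        mats = np.stack([base + 1, base - 1, base + 2, base - 2])
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1, 1, 2, 2]))
        g = build_graph(ms, t=1.0)
        np.testing.assert_allclose(g.B, 1.0)  # means coincide
        np.testing.assert_allclose(g.H @ np.ones(2), 0.0, atol=1e-12)

    def test_laplacians_psd_zero_row_sums(self):
        ms = random_matrix_set(seed=3, n_classes=3, n_per_class=4)
        g = build_graph(ms, t=1.0)
        for L in list(g.L_s) + [g.H]:
            np.testing.assert_allclose(L @ np.ones(len(L)), 0.0, atol=1e-10)
            assert np.linalg.eigvalsh(L).min() >= -1e-10

    def test_single_sample_class_rejected(self):
        mats = np.random.default_rng(1).standard_normal((3, 2, 2))
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1, 1, 2]))
        with pytest.raises(ValidationError, match="fewer than 2"):
            build_graph(ms, t=1.0)


class TestDLPP:
    def test_separated_clouds_fisher_ratio(self):
        rng = np.random.default_rng(4)
        sigma = 0.1
        mats = np.concatenate(
            [
                sigma * rng.standard_normal((10, 2, 2)),
                10 * sigma + sigma * rng.standard_normal((10, 2, 2)),
            ]
        )
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1] * 10 + [2] * 10))
        model = fit_dlpp(ms, d=1, t=1.0)
        y = transform(model, ms).ravel()
        gap = abs(y[:10].mean() - y[10:].mean())
        spread = max(y[:10].std(), y[10:].std())
        assert gap / spread > 10

    def test_duplicated_samples_same_subspace(self):
        ms = random_matrix_set(seed=5, n_f=2, n_g=3)
        dup = LabeledMatrixSet(
            matrices=np.concatenate([ms.matrices, ms.matrices]),
            labels=np.concatenate([ms.labels, ms.labels]),
        )
        m1 = fit_dlpp(ms, d=2, t=1.0)
        m2 = fit_dlpp(dup, d=2, t=1.0)
        # principal angles between the two spanned subspaces
        q1, _ = np.linalg.qr(m1.projection)
        q2, _ = np.linalg.qr(m2.projection)
        angles = np.linalg.svd(q1.T @ q2, compute_uv=False)
        np.testing.assert_allclose(angles, 1.0, atol=1e-6)

    def test_zero_dimension_rejected(self, small_set):
        with pytest.raises(ValidationError):
            fit_dlpp(small_set, d=0, t=1.0)

    def test_quadratic_form_equals_brute_force_pair_sum(self, small_set):
        """a^T X L X^T a == 1/2 sum_ij W_ij (y_i - y_j)^2 per class, for a
        generic direction a (the identity is pure Laplacian algebra)."""
        dim = small_set.n_f * small_set.n_g
        a = np.random.default_rng(14).standard_normal(dim)
        g = build_graph(small_set, t=1.0)
        for c in range(1, small_set.n_classes + 1):
            vecs = [vectorize_matrix(X) for X in small_set.class_members(c)]
            Xc = np.stack(vecs, axis=1)
            quad = a @ (Xc @ g.L_s[c - 1] @ Xc.T) @ a
            brute = oracles.dlpp_quadratic_loop(vecs, g.W_s[c - 1], a)
            assert quad == pytest.approx(brute, rel=1e-10, abs=1e-12)

    def test_sample_order_invariance(self):
        # overdetermined regime (n > N_f * N_g), the method's precondition
        ms = random_matrix_set(seed=6, n_per_class=10, n_f=3, n_g=4)
        perm = np.random.default_rng(7).permutation(ms.n_samples)
        shuffled = LabeledMatrixSet(matrices=ms.matrices[perm], labels=ms.labels[perm])
        m1 = fit_dlpp(ms, d=2, t=1.0)
        m2 = fit_dlpp(shuffled, d=2, t=1.0)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)
        for a, b in zip(m1.projection.T, m2.projection.T):
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-6)


class Test2DDLPP:
    def test_column_matrices_collapse_to_vector_dlpp(self):
        """On n x 1 matrices the left-sided row scatters equal the vector
        scatters, so 2DDLPP and DLPP share their eigenvalues."""
        rng = np.random.default_rng(8)
        mats = rng.standard_normal((12, 5, 1))
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1] * 6 + [2] * 6))
        e1 = fit_dlpp(ms, d=5, t=1.0).eigenvalues
        e2 = fit_2ddlpp(ms, d=5, t=1.0).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-8)

    def test_row_scatters_symmetric_psd(self, small_set):
        g = build_graph(small_set, t=1.0)
        P_w, P_b = _row_scatters_dlpp(small_set, g)
        for P in (P_w, P_b):
            np.testing.assert_allclose(P, P.T, atol=1e-12)
            assert np.linalg.eigvalsh(P).min() >= -1e-10

    def test_degenerate_within_scatter_still_solvable(self):
        """Identical samples per class: P_w = 0; the ridge-regularized
        solve must still return directions with small residuals."""
        A = np.arange(6.0).reshape(2, 3)
        mats = np.stack([A, A, A + 5, A + 5])
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1, 1, 2, 2]))
        model = fit_2ddlpp(ms, d=2, t=1.0)
        assert model.projection.shape == (2, 2)
        g = build_graph(ms, t=1.0)
        P_w, P_b = _row_scatters_dlpp(ms, g)
        res = eig_residuals(P_w, P_b, model.eigenvalues, model.projection)
        # residual of the regularized problem stays within contract
        assert np.all(np.isfinite(model.eigenvalues))
        assert res.max() <= 1e-6 + 1e-8 * np.abs(model.eigenvalues).max()

    def test_transform_shape_and_vectorization(self, small_set):
        model = fit_2ddlpp(small_set, d=2, t=1.0)
        out = transform(model, small_set)
        assert out.shape == (small_set.n_samples, 2 * small_set.n_g)
        Y0 = model.projection.T @ small_set.matrices[0]
        np.testing.assert_allclose(out[0], vectorize_matrix(Y0), atol=1e-12)


class TestLDA:
    def test_two_gaussians_axis(self):
        rng = np.random.default_rng(9)
        n = 40
        mats = np.zeros((2 * n, 1, 2))
        mats[:n, 0, 0] = rng.normal(0.0, 1.0, n)
        mats[n:, 0, 0] = rng.normal(10.0, 1.0, n)
        mats[:, 0, 1] = rng.normal(0.0, 1.0, 2 * n)
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1] * n + [2] * n))
        model = fit_lda(ms, d=1)
        a = model.projection[:, 0]
        assert abs(a[0]) / np.linalg.norm(a) > 0.99

    def test_rank_bound_eigenvalues(self):
        ms = random_matrix_set(seed=10, n_classes=3, n_per_class=8, n_f=2, n_g=3)
        model = fit_lda(ms, d=6)
        # between-class scatter rank <= Z - 1 = 2
        assert np.all(model.eigenvalues[2:] < 1e-8 * max(1.0, model.eigenvalues[0]))

    def test_2dlda_collapse_on_column_matrices(self):
        rng = np.random.default_rng(11)
        mats = rng.standard_normal((14, 4, 1))
        ms = LabeledMatrixSet(matrices=mats, labels=np.array([1] * 7 + [2] * 7))
        e1 = fit_lda(ms, d=4).eigenvalues
        e2 = fit_2dlda(ms, d=4).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-8)


class TestEigenContracts:
    @pytest.mark.parametrize("fitter,kind", [
        (lambda ms: fit_dlpp(ms, d=4, t=1.0), "dlpp"),
        (lambda ms: fit_2ddlpp(ms, d=3, t=1.0), "2ddlpp"),
        (lambda ms: fit_lda(ms, d=4), "lda"),
        (lambda ms: fit_2dlda(ms, d=3), "2dlda"),
    ])
    def test_eigenvalues_match_qz_brute_force(self, fitter, kind):
        """The symmetric-definite path agrees with an independent QZ solve
        of the same (regularized) matrix pencil.  Uses the overdetermined
        regime (more samples than features) where the pencil is well posed."""
        ms = random_matrix_set(seed=12, n_classes=2, n_per_class=12, n_f=3, n_g=4)
        model = fitter(ms)
        S, T = _pencil_of(ms, kind, regularized=model.fit_info.get("regularized", False))
        ref = oracles.gevp_qz(S, T)
        got = np.sort(model.eigenvalues)
        if kind in ("dlpp", "2ddlpp"):
            np.testing.assert_allclose(got, ref[: len(got)], atol=1e-6)
        else:
            np.testing.assert_allclose(got, np.sort(ref)[-len(got):], atol=1e-6)

    def test_transform_isometry_with_orthonormal_projection(self, small_set):
        """A full-rank orthonormal vector projection preserves distances."""
        from mifex.embeddings import EmbeddingModel

        dim = small_set.n_f * small_set.n_g
        rng = np.random.default_rng(13)
        Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
        model = EmbeddingModel(
            kind="dlpp", projection=Q, eigenvalues=np.zeros(dim), d=dim,
            n_f=small_set.n_f, n_g=small_set.n_g, t=1.0,
        )
        out = transform(model, small_set)
        vecs = np.stack([vectorize_matrix(X) for X in small_set.matrices])
        for i in (0, 3):
            for j in (1, 5):
                d_in = np.linalg.norm(vecs[i] - vecs[j])
                d_out = np.linalg.norm(out[i] - out[j])
                assert d_out == pytest.approx(d_in, rel=1e-10)


def _pencil_of(ms, kind, regularized):
    """Rebuild the (numerator, denominator) pencil each fit actually solved."""
    from mifex._linalg import ridge_regularize
    from mifex.embeddings import _row_scatters_dlpp, _vectorized_data

    def maybe_ridge(T):
        return ridge_regularize(T) if regularized else T

    g = build_graph(ms, t=1.0)
    if kind in ("dlpp", "lda"):
        X = _vectorized_data(ms)
        dim = X.shape[0]
        if kind == "dlpp":
            S_num = np.zeros((dim, dim))
            for c in range(1, ms.n_classes + 1):
                Xc = np.stack([vectorize_matrix(M) for M in ms.class_members(c)], axis=1)
                S_num += Xc @ g.L_s[c - 1] @ Xc.T
            F = np.stack([vectorize_matrix(M) for M in g.class_means], axis=1)
            return S_num, maybe_ridge(F @ g.H @ F.T)
        gmean = X.mean(axis=1)
        S_w = np.zeros((dim, dim))
        S_b = np.zeros((dim, dim))
        for c in range(1, ms.n_classes + 1):
            Xc = X[:, ms.labels == c]
            mc = Xc.mean(axis=1)
            R = Xc - mc[:, None]
            S_w += R @ R.T
            S_b += Xc.shape[1] * np.outer(mc - gmean, mc - gmean)
        return S_b, maybe_ridge(S_w)
    if kind == "2ddlpp":
        P_w, P_b = _row_scatters_dlpp(ms, g)
        return P_w, maybe_ridge(P_b)
    # 2dlda
    gmean = ms.matrices.mean(axis=0)
    n_f = ms.n_f
    S_w = np.zeros((n_f, n_f))
    S_b = np.zeros((n_f, n_f))
    for c in range(1, ms.n_classes + 1):
        A = ms.class_members(c)
        Fc = A.mean(axis=0)
        R = A - Fc
        S_w += np.einsum("iab,icb->ac", R, R)
        D = Fc - gmean
        S_b += len(A) * (D @ D.T)
    return S_b, maybe_ridge(S_w)
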