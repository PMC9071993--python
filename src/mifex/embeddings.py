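"""Graph-embedding projections: LDA, 2DLDA, DLPP and 2DDLPP.

Discriminant locality preserving projection (DLPP) finds directions ``a``
minimizing the heat-kernel-weighted within-class spread of the projected
samples relative to the spread of the projected class means:

    a = argmin  (a^T X L X^T a) / (a^T F H F^T a)

where ``X`` stacks the vectorized samples as columns, ``L`` is the
block-diagonal within-class graph Laplacian, ``F`` stacks the class means
and ``H = E - B`` is the Laplacian of the between-class mean graph.  The
solution directions are the smallest-eigenvalue solutions of the
generalized problem ``X L X^T a = lambda F H F^T a``.

2DDLPP is the one-sided matrix variant: samples stay ``N_f x N_g``
matrices, the scatters

    P_w = 1/2 sum_s sum_{ij} W_ij^s (X_i^s - X_j^s)(X_i^s - X_j^s)^T
    P_b = 1/2 sum_{ij} B_ij (F_i - F_j)(F_i - F_j)^T

are ``N_f x N_f`` (row side), and the transform is the left projection
``Y = A^T X``.  LDA and 2DLDA are the classical Fisher analogues
(between- over within-class scatter, largest eigenvalues).

Weights are computed over *all* within-class pairs (complete within-class
graph); an optional k-nearest-neighbor mask is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from . import _linalg
from .core import LabeledMatrixSet, ValidationError, vectorize_matrix

VECTOR_KINDS = ("lda", "dlpp")
MATRIX_KINDS = ("2dlda", "2ddlpp")


def heat_kernel_weights(items, t: float, knn: int | None = None) -> npt.NDArray[np.float64]:
    """Pairwise heat-kernel weights ``W_ij = exp(-||x_i - x_j||_F^2 / t)``.

    ``W`` is symmetric with unit diagonal.  If ``knn`` is given, weights
    outside the symmetrized k-nearest-neighbor graph are zeroed (the
    diagonal is kept).
    """
    if t <= 0:
        raise ValidationError(f"heat-kernel parameter t must be positive, got {t}")
    A = np.stack([np.asarray(x, dtype=np.float64).ravel() for x in items])
    sq = np.sum(A**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * A @ A.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    W = np.exp(-d2 / t)
    W = 0.5 * (W + W.T)
    if knn is not None:
        n = len(A)
        mask = np.zeros((n, n), dtype=bool)
        for i in range(n):
            nearest = np.argsort(d2[i], kind="stable")[: knn + 1]  # includes self
            mask[i, nearest] = True
        mask |= mask.T
        W = np.where(mask, W, 0.0)
    return W


def _laplacian(W: npt.NDArray) -> npt.NDArray[np.float64]:
    """Graph Laplacian ``L = D - W`` with ``D`` the degree matrix.

    The diagonal of ``W`` cancels out of ``L`` exactly, so it is removed
    *before* forming the degree sums: adding a unit self-weight to tiny
    off-diagonal weights (< machine epsilon) and subtracting it again
    would round the off-diagonal structure away entirely.
    """
    W_off = W - np.diag(np.diag(W))
    return np.diag(W_off.sum(axis=1)) - W_off


#: squared-distance/t threshold past which exp(-d2/t) underflows to 0.0
_UNDERFLOW_SHIFT = 500.0


def _between_weights(means: npt.NDArray, t: float) -> tuple[npt.NDArray[np.float64], float]:
    """Heat-kernel weights between class means, underflow-stabilized.

    When every pair of class means is so distant that ``exp(-d2/t)``
    underflows, all between-class structure would be lost to round-off.
    The diagonal of the between graph cancels out of its Laplacian
    ``H = E - B``, so rescaling all off-diagonal weights by a common
    positive constant only rescales the left between-class scatter (and
    its eigenvalues) uniformly — eigenvectors, the trace-normalized
    right factor and the eigenvalue-product selection order are
    unchanged.  Accordingly the minimum squared distance is subtracted
    before exponentiating whenever it would otherwise underflow; the log
    of the factored-out constant is returned for transparency.
    """
    Z = len(means)
    flat = means.reshape(Z, -1)
    sq = np.sum(flat**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * flat @ flat.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    off = d2[~np.eye(Z, dtype=bool)]
    shift = 0.0
    if Z > 1 and off.min() / t > _UNDERFLOW_SHIFT:
        shift = float(off.min())
    B = np.exp(-(d2 - shift) / t)
    np.fill_diagonal(B, 1.0)
    return 0.5 * (B + B.T), -shift / t


@dataclass(frozen=True)
class WeightGraph:
    """Within-class and between-class heat-kernel graphs of a matrix set.

    ``W_s[s]`` / ``L_s[s]`` are the weight matrix and Laplacian of class
    ``s+1``; ``B`` weighs pairs of class means, ``H = E - B`` is its
    Laplacian; ``class_means[s]`` is the mean matrix of class ``s+1``.
    """

    W_s: tuple
    L_s: tuple
    B: npt.NDArray[np.float64]
    H: npt.NDArray[np.float64]
    class_means: npt.NDArray[np.float64]
    t: float
    knn: int | None = None
    log_between_scale: float = 0.0

    @property
    def n_classes(self) -> int:
        return len(self.W_s)


def build_graph(mset: LabeledMatrixSet, t: float = 1.0, knn: int | None = None) -> WeightGraph:
    """Build the within-class graphs and the between-class mean graph."""
    Z = mset.n_classes
    if np.any(mset.class_counts < 2):
        c = 1 + int(np.argmin(mset.class_counts))
        raise ValidationError(f"class {c} has fewer than 2 samples")
    W_s, L_s = [], []
    for c in range(1, Z + 1):
        W = heat_kernel_weights(mset.class_members(c), t, knn=knn)
        W_s.append(W)
        L_s.append(_laplacian(W))
    means = mset.class_means()
    B, log_scale = _between_weights(means, t)
    return WeightGraph(
        W_s=tuple(W_s),
        L_s=tuple(L_s),
        B=B,
        H=_laplacian(B),
        class_means=means,
        t=t,
        knn=knn,
        log_between_scale=log_scale,
    )


@dataclass(frozen=True)
class EmbeddingModel:
    """A fitted linear projection with its ordered eigen-spectrum.

    ``kind`` in {"lda", "dlpp"}: ``projection`` is ``(N_f*N_g) x d`` and
    acts on vectorized samples.  ``kind`` in {"2dlda", "2ddlpp"}:
    ``projection`` is ``N_f x d`` and acts from the left, ``Y = A^T X``.
    Eigenvalues are ascending for the locality-preserving methods (the
    optimum is a minimum) and descending for the Fisher methods.
    """

    kind: str
    projection: npt.NDArray[np.float64]
    eigenvalues: npt.NDArray[np.float64]
    d: int
    n_f: int
    n_g: int
    t: float | None = None
    fit_info: dict = field(default_factory=dict)

    def output_dim(self) -> int:
        return self.d if self.kind in VECTOR_KINDS else self.d * self.n_g


def _check_d(d: int, limit: int, what: str) -> None:
    if not (1 <= d <= limit):
        raise ValidationError(f"d={d} out of range [1, {limit}] for {what}")


def _vectorized_data(mset: LabeledMatrixSet) -> npt.NDArray[np.float64]:
    """Columns = column-major vectorized samples, in sample order."""
    return np.stack([vectorize_matrix(X) for X in mset.matrices], axis=1)


def fit_dlpp(mset: LabeledMatrixSet, d: int, t: float = 1.0) -> EmbeddingModel:
    """Vector DLPP on column-major vectorized feature matrices."""
    dim = mset.n_f * mset.n_g
    _check_d(d, dim, "DLPP")
    graph = build_graph(mset, t)
    Z = mset.n_classes

    # numerator X L X^T with block-diagonal per-class Laplacian
    S_num = np.zeros((dim, dim))
    for c in range(1, Z + 1):
        Xc = np.stack([vectorize_matrix(X) for X in mset.class_members(c)], axis=1)
        S_num += Xc @ graph.L_s[c - 1] @ Xc.T
    F = np.stack([vectorize_matrix(M) for M in graph.class_means], axis=1)
    S_den = F @ graph.H @ F.T

    eigvals, eigvecs, info = _linalg.solve_gevp(
        S_num, S_den, largest=False, context="DLPP"
    )
    return EmbeddingModel(
        kind="dlpp",
        projection=eigvecs[:, :d],
        eigenvalues=eigvals[:d],
        d=d,
        n_f=mset.n_f,
        n_g=mset.n_g,
        t=t,
        fit_info=info,
    )


def _row_scatters_dlpp(mset: LabeledMatrixSet, graph: WeightGraph):
    """P_w, P_b: N_f x N_f within/between row scatters of 2DDLPP."""
    n_f = mset.n_f
    P_w = np.zeros((n_f, n_f))
    for c in range(1, mset.n_classes + 1):
        A = mset.class_members(c)
        L = graph.L_s[c - 1]
        # 1/2 sum W_ij (Xi-Xj)(Xi-Xj)^T == sum_ij L_ij Xi Xj^T
        P_w += np.einsum("ij,iab,jcb->ac", L, A, A, optimize=True)
    M = graph.class_means
    P_b = np.einsum("ij,iab,jcb->ac", graph.H, M, M, optimize=True)
    return _linalg.symmetrize(P_w), _linalg.symmetrize(P_b)


def fit_2ddlpp(mset: LabeledMatrixSet, d: int, t: float = 1.0) -> EmbeddingModel:
    """One-sided (left) 2DDLPP; ``d`` is the number of retained rows."""
    _check_d(d, mset.n_f, "2DDLPP")
    graph = build_graph(mset, t)
    P_w, P_b = _row_scatters_dlpp(mset, graph)
    eigvals, eigvecs, info = _linalg.solve_gevp(
        P_w, P_b, largest=False, context="2DDLPP"
    )
    return EmbeddingModel(
        kind="2ddlpp",
        projection=eigvecs[:, :d],
        eigenvalues=eigvals[:d],
        d=d,
        n_f=mset.n_f,
        n_g=mset.n_g,
        t=t,
        fit_info=info,
    )


def fit_lda(mset: LabeledMatrixSet, d: int) -> EmbeddingModel:
    """Classical Fisher LDA on vectorized samples (largest eigenvalues).

    The between-class scatter has rank at most Z - 1, so eigenvalues past
    that rank are numerically zero; ``d`` may still exceed it, the extra
    directions simply carry no between-class separation.
    """
    dim = mset.n_f * mset.n_g
    _check_d(d, dim, "LDA")
    X = _vectorized_data(mset)  # dim x n
    labels = mset.labels
    gmean = X.mean(axis=1)
    S_w = np.zeros((dim, dim))
    S_b = np.zeros((dim, dim))
    for c in range(1, mset.n_classes + 1):
        Xc = X[:, labels == c]
        mc = Xc.mean(axis=1)
        R = Xc - mc[:, None]
        S_w += R @ R.T
        dm = mc - gmean
        S_b += Xc.shape[1] * np.outer(dm, dm)
    eigvals, eigvecs, info = _linalg.solve_gevp(S_b, S_w, largest=True, context="LDA")
    return EmbeddingModel(
        kind="lda",
        projection=eigvecs[:, :d],
        eigenvalues=eigvals[:d],
        d=d,
        n_f=mset.n_f,
        n_g=mset.n_g,
        fit_info=info,
    )


def fit_2dlda(mset: LabeledMatrixSet, d: int) -> EmbeddingModel:
    """One-sided (left) 2DLDA: Fisher criterion on row scatters."""
    _check_d(d, mset.n_f, "2DLDA")
    n_f = mset.n_f
    gmean = mset.matrices.mean(axis=0)
    S_w = np.zeros((n_f, n_f))
    S_b = np.zeros((n_f, n_f))
    for c in range(1, mset.n_classes + 1):
        A = mset.class_members(c)
        Fc = A.mean(axis=0)
        R = A - Fc
        S_w += np.einsum("iab,icb->ac", R, R, optimize=True)
        D = Fc - gmean
        S_b += len(A) * (D @ D.T)
    eigvals, eigvecs, info = _linalg.solve_gevp(
        _linalg.symmetrize(S_b), _linalg.symmetrize(S_w), largest=True, context="2DLDA"
    )
    return EmbeddingModel(
        kind="2dlda",
        projection=eigvecs[:, :d],
        eigenvalues=eigvals[:d],
        d=d,
        n_f=mset.n_f,
        n_g=mset.n_g,
        fit_info=info,
    )


def fit_embedding(mset: LabeledMatrixSet, kind: str, d: int, t: float = 1.0) -> EmbeddingModel:
    """Dispatch to the named method ('lda', '2dlda', 'dlpp', '2ddlpp')."""
    if kind == "lda":
        return fit_lda(mset, d)
    if kind == "2dlda":
        return fit_2dlda(mset, d)
    if kind == "dlpp":
        return fit_dlpp(mset, d, t)
    if kind == "2ddlpp":
        return fit_2ddlpp(mset, d, t)
    raise ValidationError(f"unknown embedding kind {kind!r}")


def transform(model: EmbeddingModel, mset: LabeledMatrixSet) -> npt.NDArray[np.float64]:
    """Project every sample; returns an (n_samples, output_dim) array.

    Vector methods emit length-``d`` vectors; matrix methods emit the
    column-major vectorization of the ``d x N_g`` projected matrix.
    """
    if (mset.n_f, mset.n_g) != (model.n_f, model.n_g):
        raise ValidationError(
            f"set shape ({mset.n_f}, {mset.n_g}) does not match model "
            f"({model.n_f}, {model.n_g})"
        )
    A = model.projection
    if model.kind in VECTOR_KINDS:
        return _vectorized_data(mset).T @ A
    out = np.einsum("fd,ifg->idg", A, mset.matrices, optimize=True)
    return np.stack([vectorize_matrix(Y) for Y in out])
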