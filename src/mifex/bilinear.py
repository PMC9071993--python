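"""Bilinear discriminant locality preserving projection (B2DDLPP).

The one-sided 2DDLPP compresses only the row (spectral) side of the
``N_f x N_g`` spatial-spectral feature matrix.  The bilinear variant
models each class with a matrix-variate Gaussian, whose defining
property is a Kronecker-separable covariance of the vectorized data:

    vec(X) ~ N(vec(M), psi ⊗ phi)

with ``phi`` (``N_f x N_f``) the spectral (row) covariance and ``psi``
(``N_g x N_g``) the spatial (column) covariance, under column-major
vectorization.  Moment estimators of the two within-class covariance
factors are heat-kernel-weighted pair scatters,

    psi = 1/(2 N_f) sum_s sum_{ij} W_ij^s (X_i^s - X_j^s)^T (X_i^s - X_j^s)
    phi = 1/(2 N_g) sum_s sum_{ij} W_ij^s (X_i^s - X_j^s) (X_i^s - X_j^s)^T

and the between-class scatter splits into a left and right factor over
class-mean differences:

    S_BL = 1/2 sum_{ab} B_ab (F_a - F_b)(F_a - F_b)^T
    S_BR = tr(S_BL)^{-1} * 1/2 sum_{ab} B_ab (F_a - F_b)^T (F_a - F_b)

with heat-kernel weights ``B_ab = exp(-||F_a - F_b||_F^2 / t)`` between
class means.  Maximizing the between/within ratio on each side
independently gives two generalized eigenproblems,

    S_BL u = lambda phi u      (left / spectral side)
    S_BR v = gamma psi v       (right / spatial side),

both spectra sorted descending.  The bilinear transform is
``Y = U^T X V``; the ``d`` retained features are the entries ``y_lj`` of
``Y`` whose eigenvalue products ``lambda_l * gamma_j`` are largest, so
the spectral and spatial discriminability of a feature are weighed
jointly.

Notes on conventions: the covariance factors of the matrix-variate model
are mutually trace-coupled in the abstract definition, but the moment
estimators above use the fixed scalings ``1/(2 N_f)`` and ``1/(2 N_g)``;
overall scale only rescales the eigenvalues per side and leaves both
eigenvectors and the product-selection order unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from . import _linalg
from .core import LabeledMatrixSet, ValidationError
from .embeddings import WeightGraph, build_graph


@dataclass(frozen=True)
class SeparableScatter:
    """The four scatter factors of the separable discriminant model."""

    psi: npt.NDArray[np.float64]   # N_g x N_g spatial within-class covariance
    phi: npt.NDArray[np.float64]   # N_f x N_f spectral within-class covariance
    S_BL: npt.NDArray[np.float64]  # N_f x N_f between-class left factor
    S_BR: npt.NDArray[np.float64]  # N_g x N_g between-class right factor


@dataclass(frozen=True)
class BilinearModel:
    """Fitted bilinear projection.

    ``U`` (``N_f x N_f``) and ``V`` (``N_g x N_g``) hold the left/right
    generalized eigenvectors as columns, ordered by their descending
    eigenvalues ``lam`` and ``gamma``.  ``selection_order`` is the full
    permutation of (row, col) index pairs sorted by descending eigenvalue
    product ``lam[l] * gamma[j]``, ties broken by ascending ``(l, j)``.
    """

    U: npt.NDArray[np.float64]
    V: npt.NDArray[np.float64]
    lam: npt.NDArray[np.float64]
    gamma: npt.NDArray[np.float64]
    selection_order: tuple[tuple[int, int], ...]
    t: float
    ridge: float
    scatter: SeparableScatter
    fit_info: dict = field(default_factory=dict)

    @property
    def n_f(self) -> int:
        return self.U.shape[0]

    @property
    def n_g(self) -> int:
        return self.V.shape[0]


def _check_graph(mset: LabeledMatrixSet, graph: WeightGraph) -> None:
    if graph.n_classes != mset.n_classes:
        raise ValidationError(
            f"graph has {graph.n_classes} classes, set has {mset.n_classes}"
        )
    if graph.class_means.shape[1:] != (mset.n_f, mset.n_g):
        raise ValidationError("graph was built from a set of different shape")


def within_class_psi(mset: LabeledMatrixSet, graph: WeightGraph) -> npt.NDArray[np.float64]:
    """Spatial (column-side) within-class covariance, ``N_g x N_g``.

    Implements the weighted pair scatter through the Laplacian identity
    ``1/2 sum_ij W_ij (X_i - X_j)^T (X_i - X_j) = sum_ij L_ij X_i^T X_j``.
    """
    _check_graph(mset, graph)
    psi = np.zeros((mset.n_g, mset.n_g))
    for c in range(1, mset.n_classes + 1):
        A = mset.class_members(c)
        psi += np.einsum("ij,iba,jbc->ac", graph.L_s[c - 1], A, A, optimize=True)
    return _linalg.symmetrize(psi / mset.n_f)


def within_class_phi(mset: LabeledMatrixSet, graph: WeightGraph) -> npt.NDArray[np.float64]:
    """Spectral (row-side) within-class covariance, ``N_f x N_f``."""
    _check_graph(mset, graph)
    phi = np.zeros((mset.n_f, mset.n_f))
    for c in range(1, mset.n_classes + 1):
        A = mset.class_members(c)
        phi += np.einsum("ij,iab,jcb->ac", graph.L_s[c - 1], A, A, optimize=True)
    return _linalg.symmetrize(phi / mset.n_g)


def between_scatter(mset: LabeledMatrixSet, graph: WeightGraph):
    """Left and right between-class factors ``(S_BL, S_BR)``.

    ``S_BR`` carries the scalar ``1/trace(S_BL)`` so the Kronecker
    product of the two factors keeps the scale of the full between-class
    scatter.  Raises when all class means coincide (no between-class
    structure to project onto).
    """
    _check_graph(mset, graph)
    if mset.n_classes < 2:
        raise ValidationError("between-class scatter needs at least 2 classes")
    F = graph.class_means
    H = graph.H
    S_BL = _linalg.symmetrize(np.einsum("ab,aij,bkj->ik", H, F, F, optimize=True))
    tr = float(np.trace(S_BL))
    if tr <= 1e-300:
        raise ValidationError(
            "no between-class structure: all class means are identical"
        )
    S_BR = _linalg.symmetrize(np.einsum("ab,aji,bjk->ik", H, F, F, optimize=True)) / tr
    return S_BL, S_BR


def _selection_order(lam: npt.NDArray, gamma: npt.NDArray) -> tuple[tuple[int, int], ...]:
    """All (l, j) pairs by descending lam[l]*gamma[j]; ties by ascending (l, j)."""
    pairs = [
        (float(lam[l] * gamma[j]), l, j)
        for l in range(len(lam))
        for j in range(len(gamma))
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    return tuple((l, j) for _, l, j in pairs)


def fit_b2ddlpp(
    mset: LabeledMatrixSet,
    t: float = 1.0,
    ridge: float = _linalg.DEFAULT_RIDGE,
    graph: WeightGraph | None = None,
) -> BilinearModel:
    """Fit the bilinear projection on a labeled matrix set.

    Solves the two symmetric-definite generalized eigenproblems
    ``S_BL u = lambda phi u`` and ``S_BR v = gamma psi v`` with a ridge
    of ``ridge * trace/dim`` on the (possibly rank-deficient) within
    covariances, sorts both spectra descending, and precomputes the
    eigenvalue-product selection order.
    """
    if mset.n_classes < 2:
        raise ValidationError("need at least 2 classes")
    if graph is None:
        graph = build_graph(mset, t)
    psi = within_class_psi(mset, graph)
    phi = within_class_phi(mset, graph)
    S_BL, S_BR = between_scatter(mset, graph)

    phi_r = _linalg.ridge_regularize(phi, ridge)
    psi_r = _linalg.ridge_regularize(psi, ridge)
    lam, U, info_l = _linalg.solve_gevp(
        S_BL, phi_r, largest=True, ridge=ridge, context="B2DDLPP left"
    )
    gamma, V, info_r = _linalg.solve_gevp(
        S_BR, psi_r, largest=True, ridge=ridge, context="B2DDLPP right"
    )
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(gamma))):
        raise ValidationError("non-finite eigenvalues in bilinear fit")
    return BilinearModel(
        U=U,
        V=V,
        lam=lam,
        gamma=gamma,
        selection_order=_selection_order(lam, gamma),
        t=t,
        ridge=ridge,
        scatter=SeparableScatter(psi=psi, phi=phi, S_BL=S_BL, S_BR=S_BR),
        fit_info={"left": info_l, "right": info_r},
    )


def transform_b2ddlpp(
    model: BilinearModel, mset: LabeledMatrixSet, d: int
) -> npt.NDArray[np.float64]:
    """Project each sample to its ``d`` highest-priority bilinear features.

    Per trial computes ``Y = U^T X V`` and emits the entries at the first
    ``d`` positions of the model's eigenvalue-product selection order,
    in that order.  Returns an ``(n_samples, d)`` array.
    """
    n_f, n_g = model.n_f, model.n_g
    if (mset.n_f, mset.n_g) != (n_f, n_g):
        raise ValidationError(
            f"set shape ({mset.n_f}, {mset.n_g}) does not match model ({n_f}, {n_g})"
        )
    if not (1 <= d <= n_f * n_g):
        raise ValidationError(f"d={d} out of range [1, {n_f * n_g}]")
    Y = np.einsum("fl,ifg,gj->ilj", model.U, mset.matrices, model.V, optimize=True)
    rows = np.array([lj[0] for lj in model.selection_order[:d]])
    cols = np.array([lj[1] for lj in model.selection_order[:d]])
    return Y[:, rows, cols]
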