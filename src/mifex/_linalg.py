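"""Shared linear-algebra helpers: regularized symmetric-definite eigensolves.

All projection methods in this package reduce to generalized eigenvalue
problems ``S a = lambda T a`` with symmetric ``S`` and symmetric
positive-(semi)definite ``T``.  They are solved here in the
symmetric-definite form via ``scipy.linalg.eigh`` rather than by forming
``T^{-1} S``, which preserves symmetry and numerical stability; residuals
are checked against the stated contract after every solve.
"""

from __future__ import annotations

import logging

import numpy as np
import numpy.typing as npt
from scipy import linalg

logger = logging.getLogger(__name__)

#: default ridge fraction for singular denominator matrices
DEFAULT_RIDGE = 1e-6


def symmetrize(M: npt.NDArray) -> npt.NDArray[np.float64]:
    """(M + M.T) / 2 — removes round-off asymmetry before eigensolves."""
    M = np.asarray(M, dtype=np.float64)
    return 0.5 * (M + M.T)


def ridge_regularize(S: npt.NDArray, eps: float = DEFAULT_RIDGE) -> npt.NDArray[np.float64]:
    """Add ``eps * trace(S)/dim * I`` (or ``eps * I`` if trace is 0).

    Keeps the matrix scale-equivariant: the ridge is proportional to the
    mean eigenvalue, so eigenvectors of well-conditioned inputs are
    essentially unchanged.
    """
    S = symmetrize(S)
    n = S.shape[0]
    tr = float(np.trace(S))
    scale = tr / n if tr > 0 else 1.0
    return S + eps * scale * np.eye(n)


def fix_signs(vectors: npt.NDArray) -> npt.NDArray[np.float64]:
    """Flip each column so its largest-magnitude entry is positive.

    Generalized eigenvectors are only defined up to sign; fixing the sign
    makes fitted models reproducible across linear-algebra backends.
    """
    V = np.array(vectors, dtype=np.float64)
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return V


def eig_residuals(
    S: npt.NDArray, T: npt.NDArray, eigvals: npt.NDArray, eigvecs: npt.NDArray
) -> npt.NDArray[np.float64]:
    """Per-pair residual ``||S v - lambda T v||_2`` (unit-norm v)."""
    res = np.empty(len(eigvals))
    for i, (lam, v) in enumerate(zip(eigvals, eigvecs.T)):
        vn = v / np.linalg.norm(v)
        res[i] = np.linalg.norm(S @ vn - lam * (T @ vn))
    return res


def solve_gevp(
    S: npt.NDArray,
    T: npt.NDArray,
    *,
    largest: bool,
    ridge: float = DEFAULT_RIDGE,
    residual_tol: float = 1e-8,
    context: str = "",
):
    """Solve ``S a = lambda T a`` for symmetric S and PSD T.

    Parameters
    ----------
    S, T : square symmetric arrays (numerator / denominator scatters).
    largest : bool
        Sort eigenpairs by descending eigenvalue if True, ascending
        otherwise.  Ties are broken by ascending original index for
        determinism.
    ridge : float
        Ridge fraction applied to ``T`` when it is not positive definite
        (logged); 0 disables.
    residual_tol : float
        Residual contract checked against the regularized problem; the
        residual is normalized by ``max(1, ||S||_2)`` so the contract is
        scale-invariant.

    Returns
    -------
    eigvals : (n,) array, sorted per ``largest``
    eigvecs : (n, n) array, columns matching ``eigvals``, sign-fixed
    info : dict with keys ``regularized`` (bool) and ``residuals``
    """
    S = symmetrize(S)
    T = symmetrize(T)
    regularized = False
    T_eff = T
    # eigh requires positive definite b; regularize on failure or near-singularity
    try:
        cho = linalg.cholesky(T, lower=True)
        # also guard against numerically tiny pivots
        if np.min(np.abs(np.diag(cho))) < 1e-10 * max(1.0, np.abs(np.diag(cho)).max()):
            raise linalg.LinAlgError("near-singular")
    except linalg.LinAlgError:
        if ridge <= 0:
            raise
        T_eff = ridge_regularize(T, ridge)
        regularized = True
        logger.info(
            "denominator matrix singular%s; applied ridge %g * trace/dim",
            f" ({context})" if context else "",
            ridge,
        )

    eigvals, eigvecs = linalg.eigh(S, T_eff)
    # eigh returns ascending; reorder with deterministic tie-break
    order = np.argsort(-eigvals, kind="stable") if largest else np.arange(len(eigvals))
    eigvals = eigvals[order]
    eigvecs = fix_signs(eigvecs[:, order])

    res = eig_residuals(S, T_eff, eigvals, eigvecs)
    scale = max(1.0, np.linalg.norm(S, 2))
    if np.any(res / scale > residual_tol):
        raise linalg.LinAlgError(
            f"generalized eigensolve residual {res.max():.3e} exceeds "
            f"{residual_tol:.1e}{' (' + context + ')' if context else ''}"
        )
    if not np.all(np.isfinite(eigvals)):
        raise linalg.LinAlgError("non-finite eigenvalues")
    return eigvals, eigvecs, {"regularized": regularized, "residuals": res}
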