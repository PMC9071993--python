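"""One-versus-rest filter-bank CSP (OVR-FBCSP).

Common spatial patterns (CSP) finds spatial filters ``w`` that maximize
the variance of one class while minimizing that of the other, by solving
the generalized eigenproblem on trace-normalized class covariances

    C_pos w = lambda (C_pos + C_neg) w .

Eigenvalues lie in [0, 1] and measure the fraction of composite variance
explained for the positive class; the ``m`` filters from each end of the
spectrum are the most discriminative.  Features are the log of the
normalized variance of each filtered trial, which is invariant to global
trial scaling.

For ``Z > 2`` classes, CSP is applied one-versus-rest: each class in turn
is the positive partition.  Run independently in each of the ``N_f``
filter-bank bands, the per-trial output is an ``N_f x N_g`` feature
matrix with ``N_g = 2 * m * Z``: row = band, columns laid out class-major
(outer) and filter-minor (inner), the same layout in every band.  This
column layout is frozen and recorded in the model, because the bilinear
projection's column covariance is defined over these columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from . import _linalg
from .core import LabeledMatrixSet, ValidationError, from_trial_matrices
from .filterbank import BandFilteredEpochs

#: version tag of the frozen class-major/filter-minor column layout
COLUMN_LAYOUT = "class-major/filter-minor/v1"


@dataclass(frozen=True)
class CSPFilters:
    """Spatial filters for one (band, positive-class) CSP problem.

    ``W`` has shape (n_channels, 2m): columns ``0..m-1`` are the filters
    with the largest eigenvalues (maximal positive-class variance, in
    descending order), columns ``m..2m-1`` those with the smallest
    (ascending order, maximal rest-class variance).
    """

    W: npt.NDArray[np.float64]
    eigvals: npt.NDArray[np.float64]
    band_index: int
    target_class: int

    @property
    def m(self) -> int:
        return self.W.shape[1] // 2


@dataclass(frozen=True)
class OVRFBCSPModel:
    """Fitted OVR-FBCSP frontend: one CSPFilters per (band, class)."""

    filters: dict  # (band_index, class_id) -> CSPFilters
    m: int
    n_classes: int
    n_bands: int
    n_channels: int
    bands: tuple[tuple[float, float], ...]
    column_layout: str = COLUMN_LAYOUT

    @property
    def n_g(self) -> int:
        return 2 * self.m * self.n_classes


def trial_covariance(trial: npt.NDArray) -> npt.NDArray[np.float64]:
    """Trace-normalized spatial covariance ``X X^T / tr(X X^T)``."""
    C = trial @ trial.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValidationError("zero-variance trial: cannot normalize covariance")
    return C / tr


def csp_fit(
    band_trials: npt.NDArray,
    is_positive: npt.NDArray,
    m: int,
    band_index: int = 0,
    target_class: int = 1,
    ridge: float = 1e-8,
) -> CSPFilters:
    """Fit CSP filters for one binary partition of one band.

    Parameters
    ----------
    band_trials : (n_trials, n_channels, n_samples) band-filtered data.
    is_positive : boolean mask per trial; both partitions must be non-empty.
    m : filter pairs to keep; requires ``2 m <= n_channels``.
    ridge : ridge fraction applied to a rank-deficient composite
        covariance (with a log notice).
    """
    band_trials = np.asarray(band_trials, dtype=np.float64)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_trials, n_channels, _ = band_trials.shape
    if len(is_positive) != n_trials:
        raise ValidationError("mask length does not match trial count")
    if not is_positive.any() or is_positive.all():
        raise ValidationError("both CSP partitions must be non-empty")
    if 2 * m > n_channels:
        raise ValidationError(
            f"2m = {2 * m} filters requested but only {n_channels} channels"
        )

    C_pos = np.mean([trial_covariance(t) for t in band_trials[is_positive]], axis=0)
    C_neg = np.mean([trial_covariance(t) for t in band_trials[~is_positive]], axis=0)
    composite = C_pos + C_neg

    eigvals, eigvecs, _ = _linalg.solve_gevp(
        C_pos,
        composite,
        largest=True,
        ridge=ridge,
        context=f"CSP band {band_index} class {target_class}",
    )
    # descending order: first m = largest, last m reversed = smallest ascending
    W = np.concatenate([eigvecs[:, :m], eigvecs[:, -m:][:, ::-1]], axis=1)
    lam = np.concatenate([eigvals[:m], eigvals[-m:][::-1]])
    return CSPFilters(W=W, eigvals=lam, band_index=band_index, target_class=target_class)


def csp_features(trial: npt.NDArray, filters: CSPFilters) -> npt.NDArray[np.float64]:
    """Log normalized-variance features: ``log(var_k / sum_j var_j)``.

    Invariant to positive scaling of the trial.
    """
    trial = np.asarray(trial, dtype=np.float64)
    if trial.shape[0] != filters.W.shape[0]:
        raise ValidationError(
            f"trial has {trial.shape[0]} channels, filters expect {filters.W.shape[0]}"
        )
    projected = filters.W.T @ trial
    variances = projected.var(axis=1, ddof=0)
    if np.any(variances <= 0):
        k = int(np.argmin(variances))
        raise ValidationError(f"zero-variance projection for filter {k}")
    return np.log(variances / variances.sum())


def fit_ovr_fbcsp(banded: BandFilteredEpochs, m: int, ridge: float = 1e-8) -> OVRFBCSPModel:
    """Fit one CSP problem per (band, class) pair on the banded epochs."""
    labels = banded.labels
    n_classes = int(labels.max())
    if n_classes < 2:
        raise ValidationError("OVR-FBCSP requires at least 2 classes")
    filters = {}
    for b in range(banded.n_bands):
        for c in range(1, n_classes + 1):
            filters[(b, c)] = csp_fit(
                banded.data[b],
                labels == c,
                m,
                band_index=b,
                target_class=c,
                ridge=ridge,
            )
    return OVRFBCSPModel(
        filters=filters,
        m=m,
        n_classes=n_classes,
        n_bands=banded.n_bands,
        n_channels=banded.n_channels,
        bands=banded.bands,
    )


def transform_ovr_fbcsp(model: OVRFBCSPModel, banded: BandFilteredEpochs) -> LabeledMatrixSet:
    """Emit one ``N_f x N_g`` feature matrix per trial.

    Row ``b`` holds band ``b``; columns follow the frozen class-major,
    filter-minor layout recorded in the model.
    """
    if banded.n_bands != model.n_bands or banded.bands != model.bands:
        raise ValidationError("band set differs from the one the model was fit on")
    if banded.n_channels != model.n_channels:
        raise ValidationError(
            f"montage mismatch: model fit on {model.n_channels} channels, "
            f"got {banded.n_channels}"
        )
    n_g = model.n_g
    trials = []
    from .core import TrialFeatureMatrix

    for t in range(banded.n_trials):
        X = np.empty((model.n_bands, n_g))
        for b in range(model.n_bands):
            row = [
                csp_features(banded.data[b, t], model.filters[(b, c)])
                for c in range(1, model.n_classes + 1)
            ]
            X[b] = np.concatenate(row)
        assert X.shape == (model.n_bands, 2 * model.m * model.n_classes)
        trials.append(TrialFeatureMatrix(X=X, label=int(banded.labels[t])))
    return from_trial_matrices(trials)
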