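"""Core data containers for epoched EEG and spatial-spectral feature matrices.

Every downstream stage (filter bank, CSP, graph embeddings, bilinear
projections) consumes one of the three containers defined here:

``EpochedEEG``
    Trial-segmented multichannel EEG, shape ``(n_trials, n_channels,
    n_samples)``, with one integer class label per trial and a sampling
    rate in Hz.

``TrialFeatureMatrix``
    The per-trial spatial-spectral feature matrix produced by
    one-versus-rest filter-bank CSP: rows index filter-bank bands
    (``N_f``), columns index CSP log-variance features (``N_g = 2 * m *
    n_classes``).

``LabeledMatrixSet``
    A labeled collection of equally shaped feature matrices — the input
    to every projection method in this package.

Vectorization is column-major (Fortran order) throughout.  This is not a
stylistic choice: the matrix-variate Gaussian identity ``vec(X) ~
N(vec(M), psi ⊗ phi)`` with ``phi`` the row (spectral) covariance and
``psi`` the column (spatial) covariance only holds for column stacking,
and the bilinear projection's Kronecker consistency test pins the
convention down numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt


class ValidationError(ValueError):
    """Raised when input data violates a container invariant."""


@dataclass(frozen=True)
class EpochedEEG:
    """Validated trial-segmented EEG.

    Use :func:`validate_epochs` to construct; direct construction skips
    validation and is reserved for internal use on already-checked data.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial-segmented signals in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class labels, contiguous in ``{1..n_classes}``.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
    label_mapping : dict
        Original label value -> contiguous class id assigned by
        :func:`validate_epochs`.
    """

    data: npt.NDArray[np.float64]
    labels: npt.NDArray[np.int64]
    fs: float
    channel_names: list[str] | None = None
    label_mapping: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def class_counts(self) -> npt.NDArray[np.int64]:
        """Trials per class, index c-1 holds the count of class c."""
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def crop(self, start_s: float, end_s: float) -> "EpochedEEG":
        """Return a copy restricted to the window [start_s, end_s) seconds."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValidationError(
                f"crop window [{start_s}, {end_s}) s is outside the trial "
                f"({self.n_samples / self.fs:.3f} s at {self.fs} Hz)"
            )
        return EpochedEEG(
            data=self.data[:, :, i0:i1],
            labels=self.labels,
            fs=self.fs,
            channel_names=self.channel_names,
            label_mapping=self.label_mapping,
        )

    def subset(self, indices: npt.NDArray[np.int64]) -> "EpochedEEG":
        """Return a copy containing only the given trial indices."""
        idx = np.asarray(indices, dtype=np.int64)
        return EpochedEEG(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=self.channel_names,
            label_mapping=self.label_mapping,
        )


@dataclass(frozen=True)
class TrialFeatureMatrix:
    """One trial's N_f x N_g spatial-spectral feature matrix with its label."""

    X: npt.NDArray[np.float64]
    label: int

    @property
    def n_f(self) -> int:
        return self.X.shape[0]

    @property
    def n_g(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class LabeledMatrixSet:
    """A set of equally shaped labeled feature matrices.

    Attributes
    ----------
    matrices : ndarray, shape (n_samples, N_f, N_g)
    labels : ndarray of int, shape (n_samples,), values in {1..n_classes}
    """

    matrices: npt.NDArray[np.float64]
    labels: npt.NDArray[np.int64]

    def __post_init__(self) -> None:
        if self.matrices.ndim != 3:
            raise ValidationError("matrices must be a (n_samples, N_f, N_g) array")
        if len(self.labels) != self.matrices.shape[0]:
            raise ValidationError(
                f"{self.matrices.shape[0]} matrices but {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.matrices)):
            raise ValidationError("feature matrices contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_f(self) -> int:
        return self.matrices.shape[1]

    @property
    def n_g(self) -> int:
        return self.matrices.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def class_counts(self) -> npt.NDArray[np.int64]:
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def class_members(self, c: int) -> npt.NDArray[np.float64]:
        """All matrices of class c as an (n_c, N_f, N_g) array."""
        return self.matrices[self.labels == c]

    def class_means(self) -> npt.NDArray[np.float64]:
        """Per-class mean matrices, shape (n_classes, N_f, N_g)."""
        return np.stack(
            [self.class_members(c).mean(axis=0) for c in range(1, self.n_classes + 1)]
        )

    def trial_matrices(self) -> list[TrialFeatureMatrix]:
        return [
            TrialFeatureMatrix(X=self.matrices[i], label=int(self.labels[i]))
            for i in range(self.n_samples)
        ]


def from_trial_matrices(trials: list[TrialFeatureMatrix]) -> LabeledMatrixSet:
    """Assemble a LabeledMatrixSet from individual per-trial matrices."""
    if not trials:
        raise ValidationError("empty trial list")
    shapes = {t.X.shape for t in trials}
    if len(shapes) > 1:
        raise ValidationError(f"inconsistent matrix shapes: {sorted(shapes)}")
    return LabeledMatrixSet(
        matrices=np.stack([t.X for t in trials]).astype(np.float64),
        labels=np.array([t.label for t in trials], dtype=np.int64),
    )


def validate_epochs(
    raw: npt.NDArray,
    labels,
    fs: float,
    channel_names: list[str] | None = None,
    min_trial_duration_s: float = 1.0,
) -> EpochedEEG:
    """Validate raw epoched data and remap labels to contiguous {1..Z}.

    Parameters
    ----------
    raw : array_like, shape (n_trials, n_channels, n_samples)
    labels : sequence of int, one per trial
    fs : float
        Sampling rate in Hz, must be positive.
    channel_names : optional channel name list matching n_channels.
    min_trial_duration_s : float
        Minimum trial length in seconds (default 1 s).

    Returns
    -------
    EpochedEEG
        With labels remapped (order-preserving by original value) onto
        ``{1..Z}``; the bijection is stored in ``label_mapping``.

    Raises
    ------
    ValidationError
        On shape mismatch, non-finite samples (named by trial/channel),
        fewer than two classes, or any class with fewer than two trials
        (CSP and within-class scatter are undefined there).
    """
    data = np.asarray(raw, dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3-axis array, got {data.ndim} axes")
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) != data.shape[0]:
        raise ValidationError(
            f"{data.shape[0]} trials but {len(np.atleast_1d(labels))} labels"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise ValidationError("labels must be integers")
        labels = labels.astype(np.int64)
    if fs <= 0:
        raise ValidationError(f"sampling rate must be positive, got {fs}")
    if data.shape[2] < min_trial_duration_s * fs:
        raise ValidationError(
            f"trials have {data.shape[2]} samples, below the minimum "
            f"{min_trial_duration_s} s at {fs} Hz"
        )

    bad = ~np.isfinite(data)
    if bad.any():
        t, ch, _ = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite sample at trial {t}, channel {ch}"
        )

    if channel_names is not None and len(channel_names) != data.shape[1]:
        raise ValidationError(
            f"{data.shape[1]} channels but {len(channel_names)} channel names"
        )

    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError(
            f"need at least 2 classes, got {len(uniq)} (labels all {uniq[0]})"
        )
    mapping = {int(orig): i + 1 for i, orig in enumerate(uniq)}
    remapped = np.array([mapping[int(v)] for v in labels], dtype=np.int64)

    counts = np.bincount(remapped, minlength=len(uniq) + 1)[1:]
    if counts.min() < 2:
        short = uniq[int(np.argmin(counts))]
        raise ValidationError(
            f"class {short} has {counts.min()} trial(s); every class needs >= 2"
        )

    return EpochedEEG(
        data=data,
        labels=remapped,
        fs=float(fs),
        channel_names=list(channel_names) if channel_names is not None else None,
        label_mapping=mapping,
    )


def vectorize_matrix(X: npt.NDArray) -> npt.NDArray[np.float64]:
    """Column-major (Fortran-order) vectorization, ``vec(X)``.

    ``vec([[1, 3], [2, 4]]) == [1, 2, 3, 4]``; inverted exactly by
    :func:`unvectorize`.
    """
    X = np.asarray(X, dtype=np.float64)
    return X.reshape(-1, order="F")


def unvectorize(v: npt.NDArray, n_rows: int, n_cols: int) -> npt.NDArray[np.float64]:
    """Inverse of :func:`vectorize_matrix`."""
    v = np.asarray(v, dtype=np.float64)
    if v.size != n_rows * n_cols:
        raise ValidationError(f"cannot reshape length {v.size} into {n_rows}x{n_cols}")
    return v.reshape(n_rows, n_cols, order="F")
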