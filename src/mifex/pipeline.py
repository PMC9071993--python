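"""Cross-validated experiment protocol: filter bank -> OVR-FBCSP ->
feature extraction -> SVM.

The protocol mirrors standard motor-imagery practice: on the training
set, stratified k-fold cross-validation (default 5-fold) jointly selects
the CSP pair count ``m`` (grid 1..4) and the feature-space
dimensionality ``d_op`` by mean validation accuracy; the test set is then
classified once by the full pipeline refit on all training data at the
selected ``(m, d_op)``.

Leakage discipline: the filter bank is a fixed, stateless transform and
is applied once, but CSP and the feature-extraction projection are fit
exclusively on the training trials of each fold.  Every fit call is
audited — ``CVReport.fold_audit`` records the trial indices used for
fitting against the held-out indices, and ``CVReport.contamination``
counts any overlap (always zero by construction; the audit exists so
tests can prove it).

The classifier is a linear-kernel SVM with C = 1 (standard for CSP
log-variance features), preceded by per-feature standardization fit on
the fold-training split; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt
import pandas as pd
from scipy import signal
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import bilinear, embeddings
from .core import EpochedEEG, LabeledMatrixSet, ValidationError, validate_epochs, vectorize_matrix
from .fbcsp import OVRFBCSPModel, fit_ovr_fbcsp, transform_ovr_fbcsp
from .filterbank import DEFAULT_BANDS, design_filter_bank, apply_filter_bank

METHODS = ("none", "lda", "2dlda", "dlpp", "2ddlpp", "b2ddlpp")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one cross-validation / evaluation experiment.

    ``d_grid="auto"`` expands to a geometric grid of at most 40 integers
    over ``1..N_f*N_g`` for the vector and bilinear methods, and to
    ``1..N_f`` for the one-sided matrix methods.  ``m`` / ``d_op`` pin
    the operating point for :func:`evaluate_test`.
    """

    method: str = "b2ddlpp"
    m_grid: tuple[int, ...] = (1, 2, 3, 4)
    d_grid: str | tuple[int, ...] = "auto"
    n_folds: int = 5
    t: float = 1.0
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    standardize: bool = True
    seed: int = 0
    time_window_s: tuple[float, float] | None = None
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    filter_order: int = 6
    stopband_attenuation_db: float = 40.0
    zero_phase: bool = True
    m: int | None = None
    d_op: int | None = None

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if not self.m_grid or any(m_ < 1 for m_ in self.m_grid):
            raise ValidationError("m_grid must contain positive integers")
        if self.t <= 0:
            raise ValidationError("heat-kernel parameter t must be positive")


@dataclass(frozen=True)
class CVReport:
    """Cross-validation grid results.

    ``grid`` maps ``(m, d)`` to mean fold accuracy in percent (``d`` is
    ``None`` for method "none"); ``per_fold`` holds the individual fold
    accuracies.  ``best_m``/``best_d`` attain the grid maximum with ties
    broken toward smaller ``d``, then smaller ``m``.
    """

    method: str
    grid: dict
    per_fold: dict
    best_m: int
    best_d: int | None
    best_accuracy: float
    fold_audit: tuple
    contamination: int
    seed: int
    test_accuracy: float | None = None


class _Extractor:
    """Feature extractor fit once per fold at the largest requested d.

    For every method the d-dimensional feature vector is a prefix of the
    d_max-dimensional one (eigen-directions and the bilinear selection
    order are nested), so the grid over d reuses one fit.
    """

    def __init__(self, method: str, train_set: LabeledMatrixSet, d_max: int, t: float):
        self.method = method
        self.n_g = train_set.n_g
        if method == "none":
            self.model = None
        elif method == "b2ddlpp":
            self.model = bilinear.fit_b2ddlpp(train_set, t=t)
        else:
            self.model = embeddings.fit_embedding(train_set, method, d_max, t=t)
        self.d_max = d_max
        self.fit_n_samples = train_set.n_samples

    def features(self, mset: LabeledMatrixSet, d: int | None) -> npt.NDArray[np.float64]:
        if self.method == "none":
            return np.stack([vectorize_matrix(X) for X in mset.matrices])
        if self.method == "b2ddlpp":
            return bilinear.transform_b2ddlpp(self.model, mset, d)
        full = embeddings.transform(self.model, mset)
        if self.method in embeddings.VECTOR_KINDS:
            return full[:, :d]
        # one-sided matrix methods: column-major vec of the d x N_g projection.
        # vec stacks columns, so keeping the first d rows of each column means
        # keeping entries {col * d_max + row : row < d} of the full vector.
        keep = np.concatenate(
            [np.arange(d) + c * self.d_max for c in range(self.n_g)]
        )
        return full[:, keep]


def _resolve_d_grid(config: ExperimentConfig, mset: LabeledMatrixSet) -> list:
    if config.method == "none":
        return [None]
    if config.d_grid != "auto":
        limit = mset.n_f if config.method in embeddings.MATRIX_KINDS else mset.n_f * mset.n_g
        grid = sorted(set(int(d) for d in config.d_grid))
        if not grid or grid[0] < 1 or grid[-1] > limit:
            raise ValidationError(f"d_grid out of range [1, {limit}] for {config.method}")
        return grid
    if config.method in embeddings.MATRIX_KINDS:
        return list(range(1, mset.n_f + 1))
    dims = mset.n_f * mset.n_g
    return sorted(set(np.unique(np.geomspace(1, dims, num=40).round().astype(int))))


def _make_classifier(config: ExperimentConfig) -> Pipeline:
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel=config.svm_kernel, C=config.svm_C)))
    return Pipeline(steps)


def _stratified_folds(labels: npt.NDArray, n_folds: int, seed: int):
    counts = np.bincount(labels)[1:]
    if counts.min() < n_folds:
        raise ValidationError(
            f"class with {counts.min()} trials cannot be split into "
            f"{n_folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def run_cv(train: EpochedEEG, config: ExperimentConfig) -> CVReport:
    """Grid cross-validation over (m, d) on the training set."""
    config.validate()
    epochs = train
    if config.time_window_s is not None:
        epochs = epochs.crop(*config.time_window_s)
    fb = design_filter_bank(
        epochs.fs, config.bands, config.filter_order, config.stopband_attenuation_db
    )
    banded = apply_filter_bank(epochs, fb, zero_phase=config.zero_phase)
    folds = _stratified_folds(epochs.labels, config.n_folds, config.seed)

    grid: dict = {}
    per_fold: dict = {}
    audit = []
    contamination = 0
    for m in config.m_grid:
        for fold_i, (tr_idx, va_idx) in enumerate(folds):
            audit.append(
                {
                    "m": m,
                    "fold": fold_i,
                    "fit_indices": tuple(int(i) for i in sorted(tr_idx)),
                    "val_indices": tuple(int(i) for i in sorted(va_idx)),
                }
            )
            contamination += len(set(tr_idx) & set(va_idx))
            front = fit_ovr_fbcsp(banded.subset(tr_idx), m)
            set_tr = transform_ovr_fbcsp(front, banded.subset(tr_idx))
            set_va = transform_ovr_fbcsp(front, banded.subset(va_idx))
            d_values = _resolve_d_grid(config, set_tr)
            d_max = max((d for d in d_values if d is not None), default=1)
            extractor = _Extractor(config.method, set_tr, d_max, config.t)
            for d in d_values:
                X_tr = extractor.features(set_tr, d)
                X_va = extractor.features(set_va, d)
                clf = _make_classifier(config)
                clf.fit(X_tr, set_tr.labels)
                acc = 100.0 * float(np.mean(clf.predict(X_va) == set_va.labels))
                per_fold.setdefault((m, d), []).append(acc)
    for key, accs in per_fold.items():
        grid[key] = float(np.mean(accs))

    # max accuracy; ties toward smaller d, then smaller m
    def tie_key(item):
        (m, d), acc = item
        return (-acc, d if d is not None else 0, m)

    (best_m, best_d), best_acc = min(grid.items(), key=tie_key)
    return CVReport(
        method=config.method,
        grid=grid,
        per_fold=per_fold,
        best_m=best_m,
        best_d=best_d,
        best_accuracy=best_acc,
        fold_audit=tuple(audit),
        contamination=contamination,
        seed=config.seed,
    )


def evaluate_test(train: EpochedEEG, test: EpochedEEG, config: ExperimentConfig) -> float:
    """Refit the full pipeline on all training data at the fixed
    operating point ``(config.m, config.d_op)`` and score the test set.

    Returns accuracy in percent.
    """
    config.validate()
    if config.m is None:
        raise ValidationError("evaluate_test requires config.m to be fixed")
    if config.method != "none" and config.d_op is None:
        raise ValidationError("evaluate_test requires config.d_op to be fixed")
    if train.n_channels != test.n_channels:
        raise ValidationError(
            f"montage mismatch: train has {train.n_channels} channels, "
            f"test has {test.n_channels}"
        )
    tr, te = train, test
    if config.time_window_s is not None:
        tr = tr.crop(*config.time_window_s)
        te = te.crop(*config.time_window_s)
    fb = design_filter_bank(
        tr.fs, config.bands, config.filter_order, config.stopband_attenuation_db
    )
    banded_tr = apply_filter_bank(tr, fb, zero_phase=config.zero_phase)
    banded_te = apply_filter_bank(te, fb, zero_phase=config.zero_phase)
    front = fit_ovr_fbcsp(banded_tr, config.m)
    set_tr = transform_ovr_fbcsp(front, banded_tr)
    set_te = transform_ovr_fbcsp(front, banded_te)
    d = config.d_op
    extractor = _Extractor(config.method, set_tr, d if d is not None else 1, config.t)
    clf = _make_classifier(config)
    clf.fit(extractor.features(set_tr, d), set_tr.labels)
    pred = clf.predict(extractor.features(set_te, d))
    return 100.0 * float(np.mean(pred == set_te.labels))


def compare_methods(
    train: EpochedEEG,
    test: EpochedEEG | None,
    configs: dict[str, ExperimentConfig] | None = None,
    base_config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Run every method through CV (and optionally test evaluation).

    Returns one row per method with its best CV accuracy, the selected
    ``m`` and ``d_op``, and — when a test set is given — the test
    accuracy at that operating point.
    """
    if configs is None:
        base = base_config if base_config is not None else ExperimentConfig()
        configs = {meth: replace(base, method=meth) for meth in METHODS}
    rows = []
    for meth, cfg in configs.items():
        report = run_cv(train, cfg)
        row = {
            "method": meth,
            "cv_accuracy": report.best_accuracy,
            "m": report.best_m,
            "d_op": report.best_d,
        }
        if test is not None:
            fixed = replace(cfg, m=report.best_m, d_op=report.best_d)
            row["test_accuracy"] = evaluate_test(train, test, fixed)
        rows.append(row)
    return pd.DataFrame(rows)


def downsample(epochs: EpochedEEG, target_fs: float) -> EpochedEEG:
    """Anti-aliased decimation to a lower sampling rate.

    The decimation factor must be a positive integer ratio of the two
    rates (e.g. 1000 Hz -> 250 Hz).
    """
    ratio = epochs.fs / target_fs
    q = int(round(ratio))
    if q < 1 or abs(ratio - q) > 1e-9:
        raise ValidationError(
            f"sampling-rate ratio {epochs.fs}/{target_fs} is not an integer"
        )
    if q == 1:
        return epochs
    data = signal.decimate(epochs.data, q, axis=-1, ftype="iir", zero_phase=True)
    return validate_epochs(
        data, epochs.labels, target_fs, channel_names=epochs.channel_names
    )
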