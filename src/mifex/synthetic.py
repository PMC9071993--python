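"""Synthetic motor-imagery EEG and matrix-variate Gaussian generators.

Real motor imagery modulates the power of band-limited cortical rhythms:
imagining a movement suppresses the mu (8-13 Hz) and beta (14-30 Hz)
rhythm over the contralateral motor area (event-related
desynchronization, ERD).  The generator here emulates exactly the
features that variance-driven spatial filtering can recover:

* each source ``k`` is band-limited noise (white noise filtered with the
  same Chebyshev-II design as the analysis filter bank), mixed into the
  channels through a fixed unit-norm spatial pattern ``p_k``;
* class ``c`` *suppresses* its associated source by the factor
  ``1 - erd_depth`` (amplitude attenuation — ERD is a power decrease, and
  CSP is variance-driven, so phase effects are not modelled);
* spatially white broadband noise is added on every channel.

A trial of class ``c`` is thus ``sum_k a_k(c) p_k s_k(t) + noise`` with
``a_k(c) = 1 - erd_depth`` for the suppressed source and ``1``
otherwise.  The default benchmark emulates left/right-hand imagery: two
mu-band sources over disjoint channel groups, 8 channels, 250 Hz, 3 s
trials, 60 trials per class — small enough to run the full
cross-validation pipeline in seconds.  ``erd_depth=0`` (or identical
mixing) yields a null dataset whose classes are statistically
indistinguishable.

The second generator draws labeled sets of matrix-variate Gaussian
samples ``X = M_c + chol(phi) E chol(psi)^T`` with iid standard normal
``E``, so ``vec(X)`` (column-major) has covariance ``psi ⊗ phi`` — the
planted-structure testbed for the bilinear projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy import linalg, signal

from .core import EpochedEEG, LabeledMatrixSet, ValidationError, validate_epochs


def _bump_patterns(n_channels: int, n_sources: int) -> npt.NDArray[np.float64]:
    """Deterministic unit-norm spatial patterns on staggered channel groups.

    Source k is a smooth bump centered at channel (k + 1/2) * n_ch / n_src;
    for small source counts the supports barely overlap, so patterns are
    far from collinear.
    """
    centers = (np.arange(n_sources) + 0.5) * n_channels / n_sources
    width = max(n_channels / (2.5 * n_sources), 0.8)
    ch = np.arange(n_channels)
    P = np.exp(-0.5 * ((ch[None, :] - centers[:, None]) / width) ** 2)
    return P / np.linalg.norm(P, axis=1, keepdims=True)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the ERD-like synthetic EEG generator.

    ``mixing_patterns`` (n_sources x n_channels, unit rows) and
    ``source_bands`` must agree in length; class ``c`` suppresses source
    ``(c - 1) mod n_sources`` by amplitude factor ``1 - erd_depth``.
    """

    n_classes: int = 2
    n_channels: int = 8
    fs: float = 250.0
    trial_len_s: float = 3.0
    trials_per_class: int = 60
    source_bands: tuple[tuple[float, float], ...] = ((8.0, 12.0), (8.0, 12.0))
    mixing_patterns: npt.NDArray[np.float64] | None = None
    erd_depth: float = 0.7
    source_amplitude: float = 2.0
    noise_sd: float = 1.0
    filter_order: int = 6
    stopband_attenuation_db: float = 40.0
    seed: int = 0

    def resolved_patterns(self) -> npt.NDArray[np.float64]:
        if self.mixing_patterns is not None:
            return np.asarray(self.mixing_patterns, dtype=np.float64)
        return _bump_patterns(self.n_channels, len(self.source_bands))

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.n_channels < 4:
            raise ValidationError("need at least 4 channels")
        if not (0 <= self.erd_depth < 1):
            raise ValidationError(f"erd_depth must be in [0, 1), got {self.erd_depth}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.trials_per_class < 2:
            raise ValidationError("need at least 2 trials per class")
        P = self.resolved_patterns()
        if P.shape != (len(self.source_bands), self.n_channels):
            raise ValidationError(
                f"mixing_patterns shape {P.shape} does not match "
                f"({len(self.source_bands)}, {self.n_channels})"
            )
        norms = np.linalg.norm(P, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("mixing patterns must be unit norm")
        G = np.abs(P @ P.T)
        np.fill_diagonal(G, 0.0)
        # collinear patterns only make sense in a deliberate null config
        if G.max() >= 0.95 and self.erd_depth > 0:
            raise ValidationError(
                "mixing patterns are nearly collinear (|cos| >= 0.95); "
                "class structure would be unrecoverable"
            )


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A class-indistinguishable configuration (no ERD contrast)."""
    return SyntheticConfig(erd_depth=0.0, seed=seed, **overrides)


def _band_source(rng: np.random.Generator, n_samples: int, sos) -> npt.NDArray[np.float64]:
    """Unit-variance band-limited noise; padded filtering avoids edge bias."""
    pad = n_samples // 2
    x = rng.standard_normal(n_samples + 2 * pad)
    y = signal.sosfiltfilt(sos, x)[pad:-pad]
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_dataset(config: SyntheticConfig) -> EpochedEEG:
    """Draw a labeled synthetic EEG dataset; bit-reproducible given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.trial_len_s * config.fs))
    P = config.resolved_patterns()
    n_sources = len(config.source_bands)

    sos_per_source = []
    for lo, hi in config.source_bands:
        sos_per_source.append(
            signal.cheby2(
                config.filter_order // 2,
                config.stopband_attenuation_db,
                [lo, hi],
                btype="bandpass",
                fs=config.fs,
                output="sos",
            )
        )

    n_trials = config.n_classes * config.trials_per_class
    labels = np.repeat(np.arange(1, config.n_classes + 1), config.trials_per_class)
    # interleave classes so fold splits stay balanced even unshuffled
    order = rng.permutation(n_trials)
    labels = labels[order]

    data = np.zeros((n_trials, config.n_channels, n_samples))
    for t in range(n_trials):
        c = labels[t]
        suppressed = (c - 1) % n_sources
        for k in range(n_sources):
            amp = config.source_amplitude * (
                1.0 - config.erd_depth if k == suppressed else 1.0
            )
            s = _band_source(rng, n_samples, sos_per_source[k])
            data[t] += amp * np.outer(P[k], s)
        data[t] += config.noise_sd * rng.standard_normal((config.n_channels, n_samples))
    return validate_epochs(data, labels, config.fs)


def generate_matrix_gaussian_set(
    M_per_class,
    phi: npt.NDArray,
    psi: npt.NDArray,
    n_per_class: int,
    seed: int = 0,
) -> LabeledMatrixSet:
    """Sample a labeled matrix-variate Gaussian set with separable covariance.

    Parameters
    ----------
    M_per_class : sequence of N_f x N_g class-mean matrices.
    phi : N_f x N_f symmetric positive-definite row (spectral) covariance.
    psi : N_g x N_g symmetric positive-definite column (spatial) covariance.
    n_per_class : samples drawn per class.
    seed : RNG seed.

    Each sample is ``M_c + L_phi E L_psi^T`` with ``E`` iid standard
    normal and ``L`` the lower Cholesky factors, so the column-major
    ``vec(X)`` has covariance ``psi ⊗ phi``.
    """
    M_per_class = [np.asarray(M, dtype=np.float64) for M in M_per_class]
    if len(M_per_class) < 1:
        raise ValidationError("need at least one class mean")
    n_f, n_g = M_per_class[0].shape
    for M in M_per_class:
        if M.shape != (n_f, n_g):
            raise ValidationError("class means must share one shape")
    phi = np.asarray(phi, dtype=np.float64)
    psi = np.asarray(psi, dtype=np.float64)
    for name, S, dim in (("phi", phi, n_f), ("psi", psi, n_g)):
        if S.shape != (dim, dim) or not np.allclose(S, S.T, atol=1e-10):
            raise ValidationError(f"{name} must be symmetric {dim}x{dim}")
        try:
            linalg.cholesky(S, lower=True)
        except linalg.LinAlgError as err:
            raise ValidationError(f"{name} is not positive definite") from err
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")

    L_phi = linalg.cholesky(phi, lower=True)
    L_psi = linalg.cholesky(psi, lower=True)
    rng = np.random.default_rng(seed)
    mats, labels = [], []
    for c, M in enumerate(M_per_class, start=1):
        E = rng.standard_normal((n_per_class, n_f, n_g))
        mats.append(M + np.einsum("fa,iab,gb->ifg", L_phi, E, L_psi, optimize=True))
        labels.extend([c] * n_per_class)
    return LabeledMatrixSet(
        matrices=np.concatenate(mats, axis=0), labels=np.array(labels, dtype=np.int64)
    )
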