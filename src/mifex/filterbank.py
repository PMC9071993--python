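"""Chebyshev type II bandpass filter bank for motor-imagery EEG.

The default bank is the standard FBCSP layout: nine contiguous 4 Hz-wide
bands covering 4-40 Hz, which span the mu (8-13 Hz) and beta (14-30 Hz)
rhythms whose event-related (de)synchronization carries the
motor-imagery signal.  Filters are 6th-order Chebyshev type II designs
(flat passband delay, low distortion) with 40 dB stopband attenuation.

Band edges are half-power (-3 dB) specification edges: because a
Chebyshev-II design is parametrized by its stopband edges, the designer
solves for the stopband edges that place the -3 dB points of each filter
exactly on the requested band edges.

Filtering is zero-phase (forward-backward, ``sosfiltfilt``) by default so
group delay does not shift trial windows; set ``zero_phase=False`` for a
causal single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy import optimize, signal

from .core import EpochedEEG, ValidationError

#: the nine contiguous 4 Hz bands covering 4-40 Hz
DEFAULT_BANDS: tuple[tuple[float, float], ...] = tuple(
    (float(lo), float(lo + 4)) for lo in range(4, 40, 4)
)


@dataclass(frozen=True)
class FilterBank:
    """A designed bank of bandpass filters sharing one sampling rate.

    ``sos[i]`` is the second-order-section representation of the filter
    for ``bands[i]``; ``stop_edges[i]`` the solved stopband edge pair.
    """

    bands: tuple[tuple[float, float], ...]
    order: int
    stopband_attenuation_db: float
    fs: float
    sos: tuple[npt.NDArray[np.float64], ...]
    stop_edges: tuple[tuple[float, float], ...]
    design: str = "chebyshev-II"

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def frequency_response(self, band_index: int, freqs) -> npt.NDArray[np.complex128]:
        """Single-pass complex response of one filter at the given Hz values."""
        _, h = signal.sosfreqz(self.sos[band_index], worN=np.atleast_1d(freqs), fs=self.fs)
        return h


@dataclass(frozen=True)
class BandFilteredEpochs:
    """Band-decomposed epochs: shape (n_bands, n_trials, n_channels, n_samples)."""

    data: npt.NDArray[np.float64]
    labels: npt.NDArray[np.int64]
    fs: float
    bands: tuple[tuple[float, float], ...]

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def subset(self, indices) -> "BandFilteredEpochs":
        idx = np.asarray(indices, dtype=np.int64)
        return BandFilteredEpochs(
            data=self.data[:, idx], labels=self.labels[idx], fs=self.fs, bands=self.bands
        )


def _solve_stop_edges(
    low: float, high: float, order: int, rs: float, fs: float
) -> tuple[float, float]:
    """Find stopband edges putting the -3 dB points at (low, high)."""
    nyq = fs / 2.0
    half_power = 1.0 / np.sqrt(2.0)

    def resid(d):
        sos = signal.cheby2(
            order // 2, rs, [low - d[0], high + d[1]], btype="bandpass", fs=fs, output="sos"
        )
        _, h = signal.sosfreqz(sos, worN=[low, high], fs=fs)
        return np.abs(h) - half_power

    width = high - low
    lb = [1e-2, 1e-2]
    ub = [low - 0.05, nyq - high - 0.05]
    if ub[0] <= lb[0] or ub[1] <= lb[1]:
        raise ValidationError(
            f"no transition-band room for band ({low}, {high}) Hz at fs={fs} Hz"
        )
    x0 = [min(0.5 * width, 0.9 * ub[0]), min(0.5 * width, 0.9 * ub[1])]
    sol = optimize.least_squares(resid, x0=x0, bounds=(lb, ub))
    if sol.cost > 1e-10:
        raise ValidationError(
            f"could not place half-power edges for band ({low}, {high}) Hz "
            f"at fs={fs} Hz (residual {np.sqrt(2 * sol.cost):.2e})"
        )
    return float(low - sol.x[0]), float(high + sol.x[1])


def design_filter_bank(
    fs: float,
    bands=DEFAULT_BANDS,
    order: int = 6,
    stopband_attenuation_db: float = 40.0,
) -> FilterBank:
    """Design a Chebyshev-II bandpass bank with half-power edges on ``bands``.

    Parameters
    ----------
    fs : sampling rate in Hz.
    bands : ordered (low, high) pairs in Hz; all edges must lie strictly
        below the Nyquist frequency.
    order : overall filter order (even, >= 2); the bandpass design uses
        ``order // 2`` analog prototype poles.
    stopband_attenuation_db : minimum stopband attenuation in dB.

    Raises
    ------
    ValidationError
        If a band edge reaches Nyquist, the order is odd or < 2, or a
        stable design cannot be found.
    """
    if order < 2 or order % 2:
        raise ValidationError(f"order must be even and >= 2, got {order}")
    if stopband_attenuation_db <= 0:
        raise ValidationError("stopband attenuation must be positive dB")
    nyq = fs / 2.0
    bands = tuple((float(lo), float(hi)) for lo, hi in bands)
    # validate every edge before designing anything
    for lo, hi in bands:
        if not (0 < lo < hi):
            raise ValidationError(f"invalid band ({lo}, {hi})")
        if hi >= nyq:
            raise ValidationError(
                f"band edge {hi} Hz is not below Nyquist ({nyq} Hz at fs={fs})"
            )
    sos_list, edges = [], []
    for lo, hi in bands:
        wl, wh = _solve_stop_edges(lo, hi, order, stopband_attenuation_db, fs)
        sos = signal.cheby2(
            order // 2,
            stopband_attenuation_db,
            [wl, wh],
            btype="bandpass",
            fs=fs,
            output="sos",
        )
        _, poles, _ = signal.sos2zpk(sos)
        if np.abs(poles).max() >= 1.0:
            raise ValidationError(f"unstable design for band ({lo}, {hi}) Hz")
        sos_list.append(sos)
        edges.append((wl, wh))
    return FilterBank(
        bands=bands,
        order=order,
        stopband_attenuation_db=float(stopband_attenuation_db),
        fs=float(fs),
        sos=tuple(sos_list),
        stop_edges=tuple(edges),
    )


def apply_filter_bank(
    epochs: EpochedEEG, fb: FilterBank, zero_phase: bool = True
) -> BandFilteredEpochs:
    """Filter every trial and channel through every band of the bank.

    Zero-phase (default) applies each filter forward and backward, which
    squares the magnitude response (edges at -6 dB, doubled stopband
    attenuation) and cancels group delay.
    """
    if epochs.fs != fb.fs:
        raise ValidationError(
            f"epochs sampled at {epochs.fs} Hz but filter bank designed for {fb.fs} Hz"
        )
    out = np.empty((fb.n_bands, epochs.n_trials, epochs.n_channels, epochs.n_samples))
    for b, sos in enumerate(fb.sos):
        if zero_phase:
            out[b] = signal.sosfiltfilt(sos, epochs.data, axis=-1)
        else:
            out[b] = signal.sosfilt(sos, epochs.data, axis=-1)
    return BandFilteredEpochs(
        data=out, labels=epochs.labels.copy(), fs=epochs.fs, bands=fb.bands
    )
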