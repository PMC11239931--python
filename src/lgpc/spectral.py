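"""Event-related spectral perturbation (ERSP): Morlet power and dB baseline.

Per-trial time-frequency power is computed by Morlet wavelet convolution
(7-cycle wavelets, 150 center frequencies at 1-150 Hz) on 300 Hz signals
spanning -0.3 to 1.7 s around first-tone onset, then normalized per
frequency to decibels relative to the -0.3 to 0 s baseline::

    ERSP(f, t) = 10 * log10( power(f, t) / mean_{t' in baseline} power(f, t') )

The wavelet transform is delegated to :func:`mne.time_frequency.tfr_array_morlet`;
because a 7-cycle wavelet at 1 Hz (7 s) outlasts the 2 s epoch, signals are
zero-padded to cover the longest wavelet and cropped back. Bins whose
wavelet support exceeds the epoch are retained and flagged in the returned
metadata rather than masked.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import resample_poly
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import TFGrid, STANDARD_SFREQ, BASELINE_WINDOW_S

__all__ = ["morlet_tfr", "baseline_db", "MorletERSP", "resample_to"]


def morlet_tfr(signal: np.ndarray, sfreq: float = STANDARD_SFREQ,
               freqs: np.ndarray | None = None, n_cycles: float = 7.0) -> np.ndarray:
    """Morlet wavelet power of ``signal`` sampled at ``sfreq``.

    ``signal`` has shape (..., n_times); the output appends a frequency axis
    before time: (..., n_freqs, n_times). Default frequencies are 1-150 Hz
    at 1 Hz spacing (the standard grid).
    """
    from mne.time_frequency import tfr_array_morlet

    sig = np.asarray(signal, dtype=float)
    if sig.ndim == 0 or sig.shape[-1] < 2:
        raise ValueError("signal must have a time axis with at least 2 samples")
    if freqs is None:
        freqs = TFGrid.standard().freqs
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs > sfreq / 2):
        raise ValueError("frequencies must be positive and at most Nyquist")

    lead = sig.shape[:-1]
    n_times = sig.shape[-1]
    x = sig.reshape(-1, 1, n_times)

    # pad so even the longest (lowest-frequency) wavelet fits;
    # wavelet support is +-5 sigma_t with sigma_t = n_cycles / (2 pi f)
    max_len = int(np.ceil(10.0 * n_cycles / (2 * np.pi * freqs.min()) * sfreq)) + 4
    pad = max(max_len - n_times, 0)
    pad_l = pad // 2 + pad % 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad_l, pad // 2)))
    power = tfr_array_morlet(xp, sfreq=sfreq, freqs=freqs, n_cycles=n_cycles,
                             output="power", verbose="error")
    power = power[:, 0, :, pad_l:pad_l + n_times]
    return power.reshape(*lead, len(freqs), n_times)


def edge_flags(freqs: np.ndarray, n_times: int, sfreq: float = STANDARD_SFREQ,
               n_cycles: float = 7.0) -> np.ndarray:
    """Boolean flag per frequency: wavelet support exceeds the epoch length."""
    freqs = np.asarray(freqs, dtype=float)
    return n_cycles / freqs * sfreq > n_times


def baseline_db(power: np.ndarray, times: np.ndarray,
                window: tuple[float, float] = BASELINE_WINDOW_S) -> np.ndarray:
    """Per-frequency dB normalization against the mean baseline power.

    ``power`` has shape (..., n_freqs, n_times); ``times`` gives the time
    coordinate of the last axis. The baseline mean is taken within the same
    input (single-trial baseline).
    """
    power = np.asarray(power, dtype=float)
    times = np.asarray(times, dtype=float)
    if power.shape[-1] != len(times):
        raise ValueError("time axis length does not match `times`")
    lo, hi = window
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise ValueError("baseline window contains no time bins")
    base = power[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline mean power is zero for some frequency; dB undefined")
    return 10.0 * np.log10(power / base)


def resample_to(signal: np.ndarray, sfreq_in: float,
                sfreq_out: float = STANDARD_SFREQ) -> np.ndarray:
    """Polyphase resampling along the last axis (anti-aliased FIR, Kaiser window).

    Plumbing for callers holding data at acquisition rates; the analysis
    grid itself assumes 300 Hz.
    """
    from fractions import Fraction

    frac = Fraction(sfreq_out / sfreq_in).limit_denominator(10000)
    return resample_poly(signal, frac.numerator, frac.denominator, axis=-1)


class MorletERSP(TransformerMixin, BaseEstimator):
    """Transformer: trial time series -> baseline-normalized ERSP (dB).

    Parameters
    ----------
    sfreq : sampling rate of the input, Hz (the standard grid is 300 Hz).
    freqs : center frequencies; default 1-150 Hz at 1 Hz spacing.
    n_cycles : Morlet width parameter (cycles per wavelet).
    baseline : (start, stop) of the baseline window in seconds.
    epoch_start : time of the first sample relative to first-tone onset.

    ``transform`` accepts (n_trials, n_channels, n_times) or
    (n_trials, n_times) and returns dB maps with a frequency axis inserted
    before time. ``fit`` only validates parameters (stateless transform);
    after fitting, ``grid_`` holds the output :class:`~lgpc.grids.TFGrid`
    and ``edge_flags_`` marks frequencies whose wavelet outlasts the epoch.
    """

    def __init__(self, sfreq: float = STANDARD_SFREQ, freqs=None, n_cycles: float = 7.0,
                 baseline: tuple[float, float] = BASELINE_WINDOW_S,
                 epoch_start: float = -0.3):
        self.sfreq = sfreq
        self.freqs = freqs
        self.n_cycles = n_cycles
        self.baseline = baseline
        self.epoch_start = epoch_start

    def _freqs(self) -> np.ndarray:
        return (TFGrid.standard().freqs if self.freqs is None
                else np.asarray(self.freqs, dtype=float))

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim < 2:
            raise ValueError("expected at least (n_trials, n_times)")
        n_times = X.shape[-1]
        times = self.epoch_start + np.arange(n_times) / self.sfreq
        self.grid_ = TFGrid(freqs=self._freqs(), times=times)
        self.edge_flags_ = edge_flags(self.grid_.freqs, n_times, self.sfreq, self.n_cycles)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "grid_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.grid_.n_times:
            raise ValueError(
                f"expected {self.grid_.n_times} time samples, got {X.shape[-1]}")
        power = morlet_tfr(X, sfreq=self.sfreq, freqs=self.grid_.freqs,
                           n_cycles=self.n_cycles)
        return baseline_db(power, self.grid_.times, self.baseline)
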