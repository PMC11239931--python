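"""Time-frequency analysis grids.

The standard grid is 150 frequency bins (1-150 Hz, 1 Hz spacing) by 600
time bins (300 Hz sampling from -0.3 to 1.7 s relative to first-tone
onset). Tones occur at 0, 200, 400, 600 and 800 ms (50 ms tones, 150 ms
inter-tone interval), so the fifth-tone onset is 0.8 s. Reduced grids keep
the same physical epoch with coarser bins; they are used for fast
simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TFGrid", "STANDARD_SFREQ", "FIFTH_TONE_ONSET_S", "EPOCH_START_S", "EPOCH_STOP_S"]

STANDARD_SFREQ = 300.0
EPOCH_START_S = -0.3
EPOCH_STOP_S = 1.7
FIFTH_TONE_ONSET_S = 0.8
BASELINE_WINDOW_S = (-0.3, 0.0)


@dataclass(frozen=True)
class TFGrid:
    """A frequency x time grid with physical coordinates.

    ``freqs`` in Hz, ``times`` in seconds relative to first-tone onset.
    Flattening of the time-frequency dimension is frequency-major
    (index = i_freq * n_times + i_time); recorded here once so that
    flattened loadings stay portable.
    """

    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.freqs.ndim != 1 or self.times.ndim != 1:
            raise ValueError("freqs and times must be 1-D")
        if len(self.freqs) == 0 or len(self.times) == 0:
            raise ValueError("grid axes must be non-empty")

    flatten_order: str = "frequency-major"

    @property
    def n_freqs(self) -> int:
        return len(self.freqs)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_freqs, self.n_times)

    @property
    def n_tf(self) -> int:
        return self.n_freqs * self.n_times

    def baseline_mask(self, window: tuple[float, float] = BASELINE_WINDOW_S) -> np.ndarray:
        lo, hi = window
        return (self.times >= lo) & (self.times < hi)

    def post_onset_mask(self, onset_s: float = FIFTH_TONE_ONSET_S) -> np.ndarray:
        return self.times >= onset_s

    def flatten_tf(self, maps: np.ndarray) -> np.ndarray:
        """Flatten trailing (freq, time) axes frequency-major."""
        if maps.shape[-2:] != self.shape:
            raise ValueError(f"expected trailing shape {self.shape}, got {maps.shape[-2:]}")
        return maps.reshape(*maps.shape[:-2], self.n_tf)

    def unflatten_tf(self, flat: np.ndarray) -> np.ndarray:
        if flat.shape[-1] != self.n_tf:
            raise ValueError(f"expected trailing length {self.n_tf}, got {flat.shape[-1]}")
        return flat.reshape(*flat.shape[:-1], *self.shape)

    @classmethod
    def standard(cls) -> "TFGrid":
        """The 150 x 600 analysis grid."""
        n = int(round((EPOCH_STOP_S - EPOCH_START_S) * STANDARD_SFREQ))
        times = EPOCH_START_S + np.arange(n) / STANDARD_SFREQ
        return cls(freqs=np.arange(1.0, 151.0), times=times)

    @classmethod
    def reduced(cls, n_freqs: int = 20, n_times: int = 30,
                fmin: float = 5.0, fmax: float = 150.0,
                tmin: float = EPOCH_START_S, tmax: float = EPOCH_STOP_S) -> "TFGrid":
        """A coarse grid for fast simulations.

        The default window spans the whole epoch. Simulation studies that
        must still resolve closely spaced response components should zoom
        the window onto the response (e.g. the post-fifth-tone gamma
        region) rather than coarsen it below the component widths.
        """
        if n_freqs < 2 or n_times < 2:
            raise ValueError("reduced grid needs at least 2 bins per axis")
        freqs = np.linspace(fmin, fmax, n_freqs)
        times = np.linspace(tmin, tmax, n_times, endpoint=False)
        return cls(freqs=freqs, times=times)

    @classmethod
    def response_roi(cls, n_freqs: int = 20, n_times: int = 30) -> "TFGrid":
        """Reduced grid zoomed on the post-fifth-tone gamma response
        (40-150 Hz, 0.75-1.15 s): 13 ms / 5.8 Hz bins at the default size,
        fine enough to separate the PE1 and PE2 components."""
        return cls.reduced(n_freqs, n_times, fmin=40.0, fmax=150.0,
                           tmin=0.75, tmax=1.15)
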