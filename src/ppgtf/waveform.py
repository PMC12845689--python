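"""Uniformly sampled real-valued signal container.

All pipeline stages exchange :class:`Waveform` objects: the raw PPG record,
the baseline drift, the drift-free signal, band-isolated harmonics, and the
reconstructed pulse waveforms.  Time coordinates are seconds from the start
of the record; segment bounds are inclusive-start / exclusive-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Waveform"]


@dataclass
class Waveform:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples
        Signal values, arbitrary units.  Must be finite, length >= 2.
    fs
        Sampling rate in Hz, > 0.
    t0
        Time of the first sample, in seconds from the record start.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        self.fs = float(self.fs)
        self.t0 = float(self.t0)

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (self.n - 1) / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds from the record start."""
        return self.t0 + np.arange(self.n) / self.fs

    # -- derived signals ------------------------------------------------
    def copy_with(self, samples: np.ndarray) -> "Waveform":
        """New waveform on the same time base with different samples."""
        samples = np.asarray(samples, dtype=float)
        if samples.shape != self.samples.shape:
            raise ValueError("replacement samples must match length")
        return Waveform(samples, self.fs, self.t0)

    def crop(self, start_s: float, end_s: float) -> "Waveform":
        """Extract [start_s, end_s) in record time."""
        i0 = int(np.ceil((start_s - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end_s - self.t0) * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n)
        if i1 - i0 < 2:
            raise ValueError(
                f"segment [{start_s}, {end_s}) s leaves fewer than 2 samples"
            )
        return Waveform(self.samples[i0:i1].copy(), self.fs, self.t0 + i0 / self.fs)

    def trim(self, n_left: int, n_right: int) -> "Waveform":
        """Drop samples from both ends (edge-effect removal)."""
        if n_left + n_right >= self.n - 1:
            raise ValueError("trim would consume the whole waveform")
        stop = self.n - n_right if n_right else self.n
        return Waveform(
            self.samples[n_left:stop].copy(), self.fs, self.t0 + n_left / self.fs
        )

    def same_grid(self, other: "Waveform", tol: float = 1e-9) -> bool:
        """True when both waveforms share fs, t0 and length."""
        return (
            self.n == other.n
            and abs(self.fs - other.fs) <= tol * self.fs
            and abs(self.t0 - other.t0) <= tol + 0.25 / self.fs
        )
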