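"""Baseline-drift removal, heart-rate fundamental detection, and
per-harmonic band isolation.

All filtering is zero-phase (forward-backward Butterworth): the downstream
method compares instantaneous phases across harmonics, so group delay must
be null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, welch

from .waveform import Waveform

__all__ = [
    "PreprocessConfig",
    "remove_baseline",
    "detect_fundamental",
    "isolate_harmonic",
    "find_quiet_segment",
    "NoPeakError",
]

#: Physiological search band for the pulse fundamental (Hz).
F0_SEARCH_BAND = (0.7, 3.0)


class NoPeakError(ValueError):
    """No dominant spectral peak in the physiological band."""


@dataclass
class PreprocessConfig:
    """Filtering configuration.

    ``lpf_cutoff`` (Hz) separates baseline drift from the pulse band; the
    baseline filter is steeper (``lpf_order``) than the bandpass filters so
    that its skirt does not eat into the lowest pulse fundamentals.
    ``bpf_halfwidth_rel`` is the bandpass half-width as a fraction of the
    fundamental -- wide enough to pass respiratory sidebands, narrow enough
    to reject neighbouring harmonics.  ``segment`` optionally restricts the
    analysis window, (start_s, end_s), inclusive-start / exclusive-end.
    """

    lpf_cutoff: float = 0.7
    lpf_order: int = 8
    bpf_halfwidth_rel: float = 0.40
    filter_order: int = 4
    segment: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lpf_cutoff <= 0:
            raise ValueError("lpf_cutoff must be positive")
        if self.lpf_order < 1:
            raise ValueError("lpf_order must be >= 1")
        if not (0.0 < self.bpf_halfwidth_rel < 0.5):
            raise ValueError("bpf_halfwidth_rel must lie in (0, 0.5)")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def remove_baseline(
    x_ppg: Waveform, cfg: PreprocessConfig | None = None
) -> tuple[Waveform, Waveform]:
    """Split a PPG record into the drift-free signal and the baseline drift.

    ``x_b`` is the zero-phase low-pass of the record at ``lpf_cutoff``
    (drift plus DC); ``x0 = x_ppg - x_b`` is the zero-mean pulse signal.
    """
    cfg = cfg or PreprocessConfig()
    if x_ppg.duration < 10.0 / cfg.lpf_cutoff:
        raise ValueError(
            f"record of {x_ppg.duration:.1f} s is too short for the "
            f"{cfg.lpf_cutoff} Hz baseline filter to settle "
            f"(need >= {10.0 / cfg.lpf_cutoff:.1f} s)"
        )
    sos = butter(cfg.lpf_order, cfg.lpf_cutoff, btype="low", fs=x_ppg.fs, output="sos")
    xb = sosfiltfilt(sos, x_ppg.samples)
    x0 = x_ppg.samples - xb
    return x_ppg.copy_with(x0), x_ppg.copy_with(xb)


def detect_fundamental(
    x0: Waveform,
    band: tuple[float, float] = F0_SEARCH_BAND,
    min_peak_ratio: float = 4.0,
) -> float:
    """Locate the heart-rate fundamental from the averaged periodogram.

    Welch spectrum of the drift-free signal, dominant peak within ``band``,
    refined by parabolic interpolation of log power.  Raises
    :class:`NoPeakError` when the peak does not stand ``min_peak_ratio``
    times above the in-band median power (non-physiological input).
    """
    if x0.duration < 20.0:
        raise ValueError("fundamental detection needs at least 20 s of signal")
    nper = min(x0.n, int(round(20.0 * x0.fs)))
    f, p = welch(x0.samples, fs=x0.fs, nperseg=nper, detrend="constant")
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        raise NoPeakError("search band is empty at this sampling rate")
    fb, pb = f[sel], p[sel]
    j = int(np.argmax(pb))
    if pb[j] <= min_peak_ratio * np.median(pb) or pb[j] <= 0:
        raise NoPeakError(
            f"no dominant spectral peak in {band[0]}-{band[1]} Hz; "
            "input does not look like a pulse signal"
        )
    # parabolic refinement on log power (peak interior to the band)
    jg = np.flatnonzero(sel)[j]
    if 0 < jg < len(f) - 1 and p[jg - 1] > 0 and p[jg + 1] > 0:
        la, lb, lc = np.log(p[jg - 1]), np.log(p[jg]), np.log(p[jg + 1])
        denom = la - 2.0 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(fb[j] + delta * (f[1] - f[0]))


def isolate_harmonic(
    x0: Waveform, i: int, f0_est: float, cfg: PreprocessConfig | None = None
) -> Waveform:
    """Zero-phase bandpass isolation of the ``i``-th harmonic.

    Band is centred at ``i * f0_est`` with half-width
    ``bpf_halfwidth_rel * f0_est``.
    """
    cfg = cfg or PreprocessConfig()
    if i < 1:
        raise ValueError("harmonic order must be >= 1")
    if f0_est <= 0:
        raise ValueError("f0_est must be positive")
    hw = cfg.bpf_halfwidth_rel * f0_est
    # geometric centring: a Butterworth bandpass has unity gain at the
    # geometric band centre, so place that at i*f0 (band width unchanged)
    fc = i * f0_est
    hi = hw + math.sqrt(hw * hw + fc * fc)
    lo = hi - 2.0 * hw
    if hi >= x0.fs / 2.0:
        raise ValueError(
            f"harmonic {i} band [{lo:.2f}, {hi:.2f}] Hz exceeds the Nyquist "
            f"frequency {x0.fs / 2.0:.2f} Hz"
        )
    sos = butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=x0.fs, output="sos")
    return x0.copy_with(sosfiltfilt(sos, x0.samples))


def find_quiet_segment(
    wave: Waveform, length_s: float = 80.0, hop_s: float = 5.0
) -> tuple[float, float]:
    """Heuristic helper: the analysis window with the smallest amplitude jump.

    Scores each candidate window by the largest jump between consecutive
    1-s rolling RMS values and returns the (start_s, end_s) of the best one.
    Segment choice remains a manual/config decision; this only flags a
    reasonable abrupt-change-free window.
    """
    if wave.duration < length_s:
        raise ValueError("record shorter than the requested segment")
    win = max(1, int(round(wave.fs)))
    n_blocks = wave.n // win
    rms = np.sqrt(
        np.mean(wave.samples[: n_blocks * win].reshape(n_blocks, win) ** 2, axis=1)
    )
    jumps = np.abs(np.diff(rms))
    blocks_per_seg = int(round(length_s))  # 1-s blocks
    hop = max(1, int(round(hop_s)))
    best_start, best_score = 0, np.inf
    for s in range(0, n_blocks - blocks_per_seg + 1, hop):
        score = float(np.max(jumps[s : s + blocks_per_seg - 1]))
        if score < best_score:
            best_score, best_start = score, s
    start_s = wave.t0 + best_start
    return start_s, start_s + length_s
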