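"""Heart rate and heart-rate variability from the harmonic tracks, plus a
time-domain baseline (cycle segmentation, per-cycle HR, RMSSD).

Two HR readings exist per harmonic:

* ``HR_i(t) = 60 * f_i(t) / i`` from the instant frequency -- the *total*
  HR, carrying respiration, the non-harmonic physiological drive, and any
  artifact leakage into the band;
* ``HR_phi_i(t)`` from the instant initial phase -- respiration-only HR,
  since the phase residual is nearly immune to the multiplicative artifact.

HRV of a series is its RMS deviation about its own temporal mean (the only
reference available from a single segment).  Across-harmonic agreement is
summarized by the sample SD of the per-harmonic mean HRs: harmonics of one
fundamental must agree, so a large spread signals irregular rhythm and/or
artifact -- the quantity that separates AF from non-AF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .decompose import HarmonicTrack
from .preprocess import detect_fundamental
from .waveform import Waveform

__all__ = [
    "CardiacMetrics",
    "hr_from_frequency",
    "hr_summary",
    "hr_from_phase",
    "hr_phase_summary",
    "segment_cycles",
    "per_cycle_hr",
    "rmssd",
    "compute_cardiac",
    "DEFAULT_RESP_BAND",
]

#: Respiratory search band (Hz) used when reading respiration out of phase.
DEFAULT_RESP_BAND = (0.1, 0.6)


def _series_rmse(series: np.ndarray) -> float:
    """RMS deviation about the temporal mean (population SD)."""
    return float(np.std(series))


def hr_from_frequency(track: HarmonicTrack) -> tuple[np.ndarray, float]:
    """Total-HR series (bpm) and its HRV from the instant frequency."""
    hr = 60.0 * track.f / track.order
    return hr, _series_rmse(hr)


def hr_summary(tracks: list[HarmonicTrack]) -> tuple[float, float]:
    """Across-harmonic mean HR and the sample SD of per-harmonic means."""
    if len(tracks) < 2:
        raise ValueError("need at least two harmonics for an across-harmonic SD")
    means = [float(np.mean(hr_from_frequency(tr)[0])) for tr in tracks]
    return float(np.mean(means)), float(np.std(means, ddof=1))


def _bandpass_phase(
    phi0: np.ndarray, fs: float, band: tuple[float, float], order: int = 2
) -> np.ndarray:
    sos = butter(order, list(band), btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, phi0)


def hr_from_phase(
    track: HarmonicTrack,
    resp_band: tuple[float, float] = DEFAULT_RESP_BAND,
) -> tuple[np.ndarray, float]:
    """Respiration-only HR series (bpm) and its HRV from the phase residual.

    The respiratory frequency deviation is the derivative of the
    band-passed instant initial phase; division by the harmonic order maps
    every harmonic onto the same physiological HR.  A phase with no
    respiratory-band content yields a constant series (HRV 0).
    """
    dt = 1.0 / track.fs
    p = _bandpass_phase(track.phi0, track.fs, resp_band)
    if float(np.std(p)) < 1e-9:
        hr = np.full(track.n, 60.0 * track.f_mean / track.order)
        return hr, 0.0
    df = np.gradient(p, dt) / (2.0 * np.pi)
    hr = 60.0 * (track.f_mean + df) / track.order
    return hr, _series_rmse(hr)


def hr_phase_summary(
    tracks: list[HarmonicTrack],
    resp_band: tuple[float, float] = DEFAULT_RESP_BAND,
) -> tuple[float, float]:
    """Across-harmonic mean and sample SD of the respiration-only HR means."""
    if len(tracks) < 2:
        raise ValueError("need at least two harmonics for an across-harmonic SD")
    means = [float(np.mean(hr_from_phase(tr, resp_band)[0])) for tr in tracks]
    return float(np.mean(means)), float(np.std(means, ddof=1))


def segment_cycles(
    x: Waveform, f0_est: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pulse-cycle onsets and the piecewise-linear cycle baseline.

    Onsets are the local minima preceding the steepest upstrokes, found by
    derivative-peak detection with a refractory period of ``0.4 / f0``
    seconds.  Returns ``(onset_indices, baseline)`` where the baseline
    linearly connects the signal values at the onsets (for plotting and for
    per-cycle HR extraction).
    """
    s = x.samples
    if float(np.std(s)) < 1e-12:
        raise ValueError("flat signal: no pulse cycles to segment")
    if f0_est is None:
        f0_est = detect_fundamental(x)
    dt = 1.0 / x.fs
    d = np.gradient(s, dt)
    if x.fs > 24.0:  # suppress sample-to-sample noise; upstroke band is < 10 Hz
        sos = butter(2, 10.0, btype="low", fs=x.fs, output="sos")
        d = sosfiltfilt(sos, d)
    refractory = max(1, int(round(0.4 / f0_est * x.fs)))
    height = 0.3 * float(np.percentile(d, 98))
    peaks, _ = find_peaks(d, height=height, distance=refractory)
    back = max(1, int(round(0.4 / f0_est * x.fs)))
    onsets = []
    for p in peaks:
        lo = max(0, p - back)
        onsets.append(lo + int(np.argmin(s[lo : p + 1])))
    onsets = np.unique(np.asarray(onsets, dtype=int))
    if onsets.size < 5:
        raise ValueError(f"only {onsets.size} pulse cycles found (need >= 5)")
    baseline = np.interp(np.arange(x.n), onsets, s[onsets])
    return onsets, baseline


def per_cycle_hr(onsets: np.ndarray, fs: float) -> np.ndarray:
    """Per-cycle HR (bpm) from onset-to-onset intervals."""
    intervals = np.diff(onsets) / fs
    return 60.0 / intervals


def rmssd(hr_series: np.ndarray, on_intervals: bool = False) -> float:
    """Root mean square of successive differences of a per-cycle series.

    By default operates on per-cycle HR in bpm; with ``on_intervals=True``
    the series is first converted to inter-beat intervals in seconds.
    """
    hr_series = np.asarray(hr_series, dtype=float)
    if hr_series.size < 3:
        raise ValueError("RMSSD needs at least 3 cycles")
    series = 60.0 / hr_series if on_intervals else hr_series
    return float(np.sqrt(np.mean(np.diff(series) ** 2)))


@dataclass
class CardiacMetrics:
    """All HR/HRV quantities for one record segment."""

    hr_series: list[np.ndarray]  # per-harmonic total-HR series, bpm
    rmse_hr: np.ndarray  # per-harmonic total HRV, bpm
    hr: float  # mean HR across harmonics, bpm
    sd_hr: float  # across-harmonic SD of mean HR, bpm
    hr_phi_series: list[np.ndarray]  # per-harmonic respiration-only HR, bpm
    rmse_hr_phi: np.ndarray  # per-harmonic respiration-only HRV, bpm
    hr_phi: float
    sd_hr_phi: float
    td_hr: dict[str, np.ndarray] = field(default_factory=dict)  # per-cycle HR
    rmssd: dict[str, float] = field(default_factory=dict)  # per-signal RMSSD


def compute_cardiac(
    tracks: list[HarmonicTrack],
    x0: Waveform | None = None,
    f0_est: float | None = None,
    resp_band: tuple[float, float] = DEFAULT_RESP_BAND,
) -> CardiacMetrics:
    """Full cardiac-metric extraction for one segment.

    Time-domain per-cycle HR and RMSSD are computed for the drift-free
    signal ``x0`` (if given) and for the first two harmonic signals,
    mirroring the time-domain baseline comparison.
    """
    hr_series, rmse = [], []
    for tr in tracks:
        h, r = hr_from_frequency(tr)
        hr_series.append(h)
        rmse.append(r)
    hr, sd_hr = hr_summary(tracks)
    hp_series, rmse_p = [], []
    for tr in tracks:
        h, r = hr_from_phase(tr, resp_band)
        hp_series.append(h)
        rmse_p.append(r)
    hr_phi, sd_hr_phi = hr_phase_summary(tracks, resp_band)

    td_hr: dict[str, np.ndarray] = {}
    rms_sd: dict[str, float] = {}
    candidates: list[tuple[str, Waveform]] = []
    if x0 is not None:
        candidates.append(("x0", x0))
    for name, tr in zip(("x1", "x2"), tracks[:2]):
        candidates.append((name, Waveform(tr.x, tr.fs, tr.t[0])))
    for name, wave in candidates:
        try:
            onsets, _ = segment_cycles(wave, f0_est)
            series = per_cycle_hr(onsets, wave.fs)
            td_hr[name] = series
            rms_sd[name] = rmssd(series)
        except ValueError:
            continue  # too few cycles / flat: leave that variant out

    return CardiacMetrics(
        hr_series=hr_series,
        rmse_hr=np.asarray(rmse),
        hr=hr,
        sd_hr=sd_hr,
        hr_phi_series=hp_series,
        rmse_hr_phi=np.asarray(rmse_p),
        hr_phi=hr_phi,
        sd_hr_phi=sd_hr_phi,
        td_hr=td_hr,
        rmssd=rms_sd,
    )
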