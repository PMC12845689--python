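"""Hilbert-based extraction of per-harmonic instant amplitude, frequency
and initial phase, plus sensor-noise estimation.

Each band-isolated harmonic is treated as a mono-component signal.  Its
analytic signal yields the envelope ``A(t)`` and unwrapped phase ``Phi(t)``;
the instant frequency ``f(t)`` is the smoothed phase derivative, and the
instant initial phase ``phi0(t)`` is the phase residual about the
segment-mean frequency:

    Phi(t) = 2*pi*f_mean*(t - t_start) + phi0(t) + 2*pi*k

``phi0(t)`` therefore carries the integrated respiratory frequency
modulation as a clean, slowly varying near-sinusoid, which is why
respiration is best read from it.  ``f(t)`` carries the same modulation
plus the non-harmonic physiological drive and whatever the motion artifact
leaks into the band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .waveform import Waveform

__all__ = [
    "DecomposeConfig",
    "HarmonicTrack",
    "Decomposition",
    "hvd_track",
    "assemble",
    "smoothing_gain",
]


@dataclass
class DecomposeConfig:
    """Instant-parameter extraction settings.

    ``freq_smooth_cutoff`` (Hz) low-passes the raw phase derivative: it must
    sit above the respiratory band (so respiratory FM survives) but low
    enough to suppress derivative noise.  ``edge_trim_s`` removes Hilbert
    end effects from every track.  ``weak_rel_eps`` defines envelope
    collapse relative to the band signal RMS.
    """

    freq_smooth_cutoff: float = 0.5
    smooth_order: int = 4
    edge_trim_s: float = 2.0
    weak_rel_eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.freq_smooth_cutoff <= 0:
            raise ValueError("freq_smooth_cutoff must be positive")
        if self.edge_trim_s < 0:
            raise ValueError("edge_trim_s must be non-negative")


def smoothing_gain(cutoff: float, order: int, f: float) -> float:
    """Amplitude gain of the zero-phase frequency smoother at ``f`` Hz.

    Forward-backward Butterworth: |H|^2 of the one-pass filter, i.e.
    ``1 / (1 + (f/cutoff)**(2*order))``.  Stored with each track so that
    respiration amplitudes read from f(t) can be bias-corrected if desired.
    """
    return 1.0 / (1.0 + (f / cutoff) ** (2 * order))


@dataclass
class HarmonicTrack:
    """Instant parameters of one harmonic on a common trimmed time base.

    ``phase`` is the unwrapped analytic phase; the definitional split
    ``phase = 2*pi*f_mean*(t - t[0]) + phi0 + phase_offset`` holds exactly,
    as does the Hilbert identity ``x = A * cos(phase)``.
    """

    order: int
    t: np.ndarray  # seconds from record start
    A: np.ndarray  # instant amplitude, a.u.
    f: np.ndarray  # instant frequency, Hz (smoothed)
    phi0: np.ndarray  # instant initial phase, rad
    x: np.ndarray  # band-isolated harmonic signal
    phase: np.ndarray  # unwrapped analytic phase, rad
    fs: float
    f_mean: float  # segment-mean instant frequency, Hz
    phase_offset: float  # constant absorbed by the wrap-correction, rad
    trim: int  # samples trimmed from each end of the source segment
    weak: bool = False  # envelope-collapse flag
    smoother_gain_at: object = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.t.size

    def reconstruction(self) -> np.ndarray:
        """A(t)*cos(2*pi*f_mean*(t-t0) + phi0(t) + offset) -- equals x."""
        arg = (
            2.0 * np.pi * self.f_mean * (self.t - self.t[0])
            + self.phi0
            + self.phase_offset
        )
        return self.A * np.cos(arg)


@dataclass
class Decomposition:
    """All harmonic tracks plus the derived composite and noise signals.

    ``x_hvd = sum_i x_i`` and ``x_noise = x0 - x_hvd`` sample-wise, both
    exact by construction on the common trimmed time base.
    """

    x0: Waveform  # drift-free signal, trimmed to the track time base
    tracks: list[HarmonicTrack]
    x_hvd: Waveform
    x_noise: Waveform
    noise_rms_rel: float  # RMS(x_noise) / RMS(x0)


def hvd_track(
    x_sd_i: Waveform,
    i: int,
    f0_est: float,
    cfg: DecomposeConfig | None = None,
) -> HarmonicTrack:
    """Extract instant amplitude / frequency / initial phase of harmonic ``i``.

    ``x_sd_i`` must be the band-isolated harmonic.  ``f0_est`` is used only
    for sanity context; the track's own mean frequency is measured from the
    data.  Edge samples (``cfg.edge_trim_s`` per side) are trimmed from all
    outputs to remove Hilbert end effects.
    """
    cfg = cfg or DecomposeConfig()
    fs = x_sd_i.fs
    dt = 1.0 / fs
    z = hilbert(x_sd_i.samples)
    a_raw = np.abs(z)
    phase_raw = np.unwrap(np.angle(z))
    f_raw = np.gradient(phase_raw, dt) / (2.0 * np.pi)

    k = int(round(cfg.edge_trim_s * fs))
    if 2 * k >= x_sd_i.n - 2:
        raise ValueError("edge trim consumes the whole segment")
    sl = slice(k, x_sd_i.n - k if k else x_sd_i.n)
    t = x_sd_i.t[sl]
    a = a_raw[sl]
    phase = phase_raw[sl]
    x = x_sd_i.samples[sl]
    # trim the Hilbert end effects *before* smoothing, so the smoother's
    # reflection padding sees valid data instead of the edge transient
    sos = butter(cfg.smooth_order, cfg.freq_smooth_cutoff, btype="low", fs=fs, output="sos")
    f = sosfiltfilt(sos, f_raw[sl])

    f_mean = float(np.mean(f))
    resid = phase - 2.0 * np.pi * f_mean * (t - t[0])
    offset = 2.0 * np.pi * round(float(np.mean(resid)) / (2.0 * np.pi))
    phi0 = resid - offset

    rms = math.sqrt(float(np.mean(x**2)))
    eps = cfg.weak_rel_eps * rms
    weak = rms == 0.0 or float(np.mean(a < eps)) > 0.10

    return HarmonicTrack(
        order=i,
        t=t,
        A=a,
        f=f,
        phi0=phi0,
        x=x,
        phase=phase,
        fs=fs,
        f_mean=f_mean,
        phase_offset=float(offset),
        trim=k,
        weak=weak,
        smoother_gain_at=lambda fq, _c=cfg: smoothing_gain(
            _c.freq_smooth_cutoff, _c.smooth_order, fq
        ),
    )


def assemble(x0: Waveform, tracks: list[HarmonicTrack]) -> Decomposition:
    """Combine tracks into the composite signal and the noise estimate.

    All tracks must share one trimmed time base derived from ``x0``;
    ``x0`` is trimmed to match before the (exact) subtraction.
    """
    if not tracks:
        raise ValueError("need at least one track")
    n = tracks[0].n
    k = tracks[0].trim
    for tr in tracks[1:]:
        if tr.n != n or tr.trim != k:
            raise ValueError("tracks do not share a common trimmed time base")
    if x0.n != n + 2 * k:
        raise ValueError("x0 length does not match the tracks' source segment")
    x0_trim = x0.trim(k, k) if k else x0
    xhvd = np.sum([tr.x for tr in tracks], axis=0)
    xnoise = x0_trim.samples - xhvd
    rms0 = math.sqrt(float(np.mean(x0_trim.samples**2)))
    rel = math.sqrt(float(np.mean(xnoise**2))) / rms0 if rms0 > 0 else 0.0
    return Decomposition(
        x0=x0_trim,
        tracks=tracks,
        x_hvd=x0_trim.copy_with(xhvd),
        x_noise=x0_trim.copy_with(xnoise),
        noise_rms_rel=rel,
    )
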