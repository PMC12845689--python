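"""Motion-artifact removal and pulse-waveform reconstruction.

From each harmonic track the slow amplitude trend (a least-squares
regression line) and the mean initial phase are taken; the pulse is then
re-synthesized in two variants:

* ``x_tf`` -- time-varying frequency: keeps the measured instant frequency
  of every harmonic, so heart-rate variability survives, while the TVSP
  amplitude swing and phase noise are replaced by the trend line and the
  mean phase.
* ``x_cf`` -- constant frequency: every harmonic runs at ``i * f0``, which
  shows what the pulse would look like with a perfectly steady heart rate.

The TVSP distortion estimate is the difference ``x_tvsp = x_hvd - x_tf``.
Arterial-pulse-waveform (APW) shape features are the harmonic amplitude
ratios and initial-phase differences relative to the first harmonic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .decompose import Decomposition, HarmonicTrack
from .waveform import Waveform

__all__ = [
    "Reconstruction",
    "amplitude_trend",
    "phase_mean",
    "reconstruct_tf",
    "reconstruct_cf",
    "apw_features",
    "build_reconstruction",
    "wrap_phase",
]


def wrap_phase(phi: float | np.ndarray):
    """Wrap angle(s) to (-pi, pi]."""
    out = np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi)
    out = np.pi - out
    return float(out) if np.isscalar(phi) else out


@dataclass
class Reconstruction:
    """Reconstructed waveforms and APW shape features."""

    A_tilde: list[np.ndarray]  # per-harmonic regression-line amplitudes
    phi_bar: list[float]  # per-harmonic mean initial phases, rad
    x_tf: Waveform  # time-varying-frequency reconstruction
    x_cf: Waveform  # constant-frequency reconstruction
    x_tvsp: Waveform  # TVSP distortion estimate: x_hvd - x_tf
    amp_ratio: np.ndarray  # mean(A~_i)/mean(A~_1), i = 2..N
    phase_diff: np.ndarray  # wrap(phi_bar_i - phi_bar_1), i = 2..N
    phi3_gt_phi2: bool | None  # mean phase of harmonic 3 exceeds harmonic 2


def amplitude_trend(track: HarmonicTrack) -> np.ndarray:
    """First-degree least-squares fit of A(t), evaluated on the time base."""
    coef = np.polyfit(track.t, track.A, 1)
    return np.polyval(coef, track.t)


def phase_mean(track: HarmonicTrack) -> float:
    """Circular-safe mean of the instant initial phase, in (-pi, pi].

    phi0(t) is a continuous residual (already unwrap-corrected), so the
    plain temporal mean is taken and then wrapped.
    """
    return wrap_phase(float(np.mean(np.unwrap(track.phi0))))


def _anchor(track: HarmonicTrack, phi_bar_i: float) -> tuple[np.ndarray, float]:
    """Cycle integral of f(t) and its phase-alignment constant.

    The integration constant makes the circular-mean discrepancy between
    the synthetic phase ``2*pi*int(f) + phi_bar_i + c`` and the measured
    analytic phase vanish, keeping the reconstruction in register with
    x_hvd so that their residual is pure artifact/noise rather than a
    constant phase offset.
    """
    ci = cumulative_trapezoid(track.f, track.t, initial=0.0)
    resid = track.phase - 2.0 * np.pi * ci - phi_bar_i
    c0 = float(np.angle(np.mean(np.exp(1j * resid))))
    return ci, phi_bar_i + c0


def reconstruct_tf(
    tracks: list[HarmonicTrack],
    A_tilde: list[np.ndarray],
    phi_bar: list[float],
) -> Waveform:
    """Sum of A~_i(t) * cos(2*pi*integral(f_i) + phi_bar_i)."""
    ref = tracks[0]
    out = np.zeros(ref.n)
    for tr, a_line, pb in zip(tracks, A_tilde, phi_bar):
        ci, c0 = _anchor(tr, pb)
        out += a_line * np.cos(2.0 * np.pi * ci + c0)
    return Waveform(out, ref.fs, ref.t[0])


def reconstruct_cf(
    tracks: list[HarmonicTrack],
    A_tilde: list[np.ndarray],
    phi_bar: list[float],
    f0_est: float,
) -> Waveform:
    """Sum of A~_i(t) * cos(2*pi*i*f0*t + phi_bar_i), phase-aligned to x_hvd."""
    ref = tracks[0]
    t = ref.t
    out = np.zeros(ref.n)
    for tr, a_line, pb in zip(tracks, A_tilde, phi_bar):
        ramp = 2.0 * np.pi * tr.order * f0_est * (t - t[0])
        resid = tr.phase - ramp - pb
        c0 = float(np.angle(np.mean(np.exp(1j * resid))))
        out += a_line * np.cos(ramp + pb + c0)
    return Waveform(out, ref.fs, t[0])


def apw_features(recon: "Reconstruction") -> tuple[np.ndarray, np.ndarray]:
    """Harmonic amplitude ratios and phase differences relative to harmonic 1."""
    return recon.amp_ratio, recon.phase_diff


def build_reconstruction(decomp: Decomposition, f0_est: float) -> Reconstruction:
    """Run the full reconstruction stage on a decomposition."""
    tracks = decomp.tracks
    a_tilde = [amplitude_trend(tr) for tr in tracks]
    phi_bar = [phase_mean(tr) for tr in tracks]
    x_tf = reconstruct_tf(tracks, a_tilde, phi_bar)
    x_cf = reconstruct_cf(tracks, a_tilde, phi_bar, f0_est)
    x_tvsp = decomp.x_hvd.copy_with(decomp.x_hvd.samples - x_tf.samples)

    means = np.array([float(np.mean(a)) for a in a_tilde])
    if means[0] <= 0:
        ratios = np.full(max(len(tracks) - 1, 0), np.nan)
    else:
        ratios = means[1:] / means[0]
    diffs = wrap_phase(np.asarray(phi_bar[1:]) - phi_bar[0]) if len(phi_bar) > 1 else np.array([])
    flag = None
    if len(phi_bar) >= 3:
        flag = bool(wrap_phase(phi_bar[2] - phi_bar[1]) > 0.0)
    return Reconstruction(
        A_tilde=a_tilde,
        phi_bar=phi_bar,
        x_tf=x_tf,
        x_cf=x_cf,
        x_tvsp=x_tvsp,
        amp_ratio=ratios,
        phase_diff=np.asarray(diffs),
        phi3_gt_phi2=flag,
    )
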