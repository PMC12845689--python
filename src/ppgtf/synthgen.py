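"""Forward simulator of motion artifact in an at-rest PPG signal.

The tissue-contact-sensor (TCS) stack between the artery and the PPG sensor
is modelled as a base-excited single-degree-of-freedom (SDOF) oscillator
with nominal mass ``m0``, damping ``c0`` and stiffness ``k0``.  Motion
artifact enters twice:

* **baseline drift** ``x_b(t)`` -- a low-frequency (< 0.7 Hz) additive
  displacement of the sensor relative to the artery, and
* **time-varying system parameters (TVSP)** -- ``m(t), c(t), k(t)``
  proportional to the drift, which turn the oscillator response into a
  multiplicative distortion riding on every harmonic of the pulse.

The true arterial pulse ``y(t)`` is a sum of harmonics of the heart rate
whose instantaneous frequency is modulated by respiration (respiratory
sinus arrhythmia, amplitude ``B`` at rate ``f_r``) and by a non-harmonic
"physiological factor" process (an Ornstein-Uhlenbeck-style smoothed
Gaussian drive).  The simulator integrates the oscillator at the signal
sampling rate and keeps every ground-truth component, so the analysis
pipeline can be validated against known truth.

Atrial fibrillation (AF) is emulated by large, irregular beat-to-beat
frequency variation (large ``pf_sd``) and harmonic-wise inconsistent
respiration modulation; the non-AF preset has small, coherent modulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, lfilter, sosfiltfilt

from .waveform import Waveform

__all__ = [
    "TruePulseSpec",
    "SDOFConfig",
    "SyntheticRecord",
    "SimulationError",
    "closed_form_gain",
    "make_true_pulse",
    "true_instant_frequencies",
    "make_baseline_drift",
    "simulate_tcs",
    "make_ppg",
    "generate_cohort",
    "nonaf_preset",
    "af_preset",
    "TRANSIENT_S",
]

#: Start-up transient of the SDOF integration, discarded before analysis (s).
TRANSIENT_S = 5.0

#: Upper frequency bound of baseline drift (Hz).
DRIFT_BAND_HZ = 0.7


class SimulationError(RuntimeError):
    """Invalid parameters or diverged/unstable integration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TruePulseSpec:
    """Generative parameters of the true arterial pulse y(t).

    y(t) = sum_i A_i cos(Theta_i(t)) with
    dTheta_i/dt = 2*pi * i * (f0 + B_i cos(2*pi*f_r*t + alpha_i) + PF(t))

    when ``order_scaling`` is True (the default); with it off the modulation
    term is not multiplied by the harmonic order i.  ``PF(t)`` is a zero-mean
    Ornstein-Uhlenbeck process with stationary SD ``pf_sd`` and correlation
    time ``pf_corr_time`` shared by all harmonics.

    ``B_jitter`` / ``alpha_jitter`` give each harmonic its own respiration
    modulation amplitude ``B_i = B * B_jitter[i-1]`` and phase
    ``alpha_i = alpha0 + alpha_jitter[i-1]`` -- the AF preset uses these to
    break the harmonic-wise coherence of respiration.
    """

    f0: float = 1.2  # fundamental (heart) frequency, Hz
    N: int = 3  # number of harmonics
    A: Sequence[float] = (1.0, 0.5, 0.25)  # harmonic amplitudes, a.u.
    phi0: Sequence[float] = (0.0, 0.3, 0.1)  # harmonic initial phases, rad
    B: float = 0.0  # respiration modulation amplitude, Hz
    f_r: float = 0.25  # respiration rate, Hz
    alpha0: float = 0.0  # respiration initial phase, rad
    pf_sd: float = 0.0  # SD of physiological-factor frequency perturbation, Hz
    pf_corr_time: float = 5.0  # correlation time of that perturbation, s
    order_scaling: bool = True
    B_jitter: Sequence[float] | None = None
    alpha_jitter: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.phi0 = np.asarray(self.phi0, dtype=float)
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.N < 1:
            raise ValueError("need at least one harmonic")
        if len(self.A) < self.N or len(self.phi0) < self.N:
            raise ValueError("A and phi0 must provide one entry per harmonic")
        if np.any(self.A[: self.N] < 0):
            raise ValueError("harmonic amplitudes must be non-negative")
        if not (0 <= self.f_r < self.f0):
            raise ValueError("respiration rate must satisfy 0 <= f_r < f0")
        if self.B < 0 or self.pf_sd < 0:
            raise ValueError("B and pf_sd must be non-negative")
        if self.B_jitter is not None:
            self.B_jitter = np.asarray(self.B_jitter, dtype=float)
        if self.alpha_jitter is not None:
            self.alpha_jitter = np.asarray(self.alpha_jitter, dtype=float)

    def harmonic_B(self, i: int) -> float:
        b = self.B if self.B_jitter is None else self.B * float(self.B_jitter[i - 1])
        return b

    def harmonic_alpha(self, i: int) -> float:
        a = self.alpha0
        if self.alpha_jitter is not None:
            a = a + float(self.alpha_jitter[i - 1])
        return a


@dataclass
class SDOFConfig:
    """Nominal oscillator parameters, TVSP coupling, drift and noise.

    The time-varying parameters follow the drift linearly:
    ``m(t) = m0 * (1 + gamma_m * x_b(t) / x_b_scale)`` and likewise for
    ``c(t)`` and ``k(t)``.  ``drift_sinusoids`` is a list of
    ``(frequency_hz, amplitude, phase_rad)`` tuples (all frequencies below
    0.7 Hz); ``drift_walk_amp`` adds a band-limited random walk with that
    RMS amplitude.  ``noise_sd`` is the additive white sensor-noise SD.

    Defaults place the contact natural frequency at 2 Hz -- inside the
    pulse band, where the harmonics sit on and above the resonance -- with
    30% of critical damping.  Above the resonance the transmissibility is
    approximately k(t)/(m w^2), so stiffness variation rides directly on
    each harmonic as multiplicative distortion; a much stiffer contact
    would transmit unity at all harmonics and produce no appreciable
    distortion.  The physical values of the TCS stack cannot be identified
    from a single pulse signal, so these are simulator conventions, not
    measurements.
    """

    m0: float = 1.0
    c0: float | None = None  # default: 30% of critical damping
    k0: float = (2.0 * math.pi * 2.0) ** 2  # natural frequency 2 Hz for m0=1
    gamma_m: float = 0.0
    gamma_c: float = 0.0
    gamma_k: float = 0.0
    x_b_scale: float = 1.0
    drift_sinusoids: Sequence[tuple[float, float, float]] = ()
    drift_walk_amp: float = 0.0
    drift_walk_cutoff: float = 0.35  # Hz, band limit of the random walk
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.m0 <= 0 or self.k0 <= 0:
            raise ValueError("m0 and k0 must be positive")
        if self.c0 is None:
            self.c0 = 0.3 * 2.0 * math.sqrt(self.k0 * self.m0)
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")
        if self.x_b_scale <= 0:
            raise ValueError("x_b_scale must be positive")
        for f_hz, _amp, _ph in self.drift_sinusoids:
            if f_hz >= DRIFT_BAND_HZ:
                raise ValueError(
                    f"drift sinusoid at {f_hz} Hz is not baseline drift "
                    f"(must be < {DRIFT_BAND_HZ} Hz)"
                )
        if not (0 < self.drift_walk_cutoff < DRIFT_BAND_HZ):
            raise ValueError("drift_walk_cutoff must lie in (0, 0.7) Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticRecord:
    """A simulated PPG record with full ground truth.

    ``ppg.samples == x_m + x_b + x_noise_true`` sample-wise, where
    ``x_m = x_c + x_tvsp_true`` (the oscillator response splits into the
    constant-parameter response ``x_c`` and the TVSP distortion).
    """

    ppg: Waveform
    y: Waveform  # true arterial pulse (base excitation)
    x_b: Waveform  # baseline drift
    x_m: Waveform  # oscillator (mass) displacement, TVSP on
    x_c: Waveform  # oscillator displacement with constant parameters
    x_tvsp_true: Waveform  # x_m - x_c
    x_noise_true: Waveform  # additive sensor noise
    spec: TruePulseSpec
    sdof: SDOFConfig
    label: str = "non-AF"  # "AF" | "non-AF"
    seed: int = 0
    subject_id: str = ""


# ---------------------------------------------------------------------------
# Closed-form constant-parameter response
# ---------------------------------------------------------------------------


def closed_form_gain(
    m0: float, c0: float, k0: float, omega_y: float
) -> tuple[float, float]:
    """Steady-state gain and phase of the base-excited SDOF oscillator.

    Returns the modulus ``G0`` and argument ``phi0_shift`` (in (-pi, pi])
    of ``(k0 + j*c0*w) / (k0 - m0*w**2 + j*c0*w)`` -- the transfer from the
    arterial-wall displacement to the mass displacement at angular
    frequency ``omega_y``.
    """
    if m0 < 0 or k0 <= 0 or c0 < 0 or omega_y < 0:
        raise ValueError("require m0 >= 0, k0 > 0, c0 >= 0, omega_y >= 0")
    denom = complex(k0 - m0 * omega_y**2, c0 * omega_y)
    if abs(denom) == 0.0:
        raise SimulationError(
            "undamped resonance: c0 = 0 with omega_y = sqrt(k0/m0) "
            "has unbounded steady-state response"
        )
    h = complex(k0, c0 * omega_y) / denom
    phase = math.atan2(h.imag, h.real)
    if phase <= -math.pi:  # atan2 returns (-pi, pi]; keep the convention explicit
        phase += 2.0 * math.pi
    return abs(h), phase


# ---------------------------------------------------------------------------
# True pulse
# ---------------------------------------------------------------------------


def _ou_process(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (exact discretization)."""
    if sd == 0.0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    drive = sd * math.sqrt(1.0 - a * a) * rng.standard_normal(n)
    drive[0] = sd * rng.standard_normal()  # stationary start
    return lfilter([1.0], [1.0, -a], drive)


def true_instant_frequencies(
    spec: TruePulseSpec, fs: float, duration: float, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth instantaneous frequency of each harmonic.

    Returns ``(t, F)`` with ``F[i-1]`` the instantaneous frequency (Hz) of
    harmonic ``i`` on the time axis ``t``.  The physiological-factor process
    is reproducible from ``seed``.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short")
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    pf = _ou_process(n, 1.0 / fs, spec.pf_sd, spec.pf_corr_time, rng)
    freqs = np.empty((spec.N, n))
    for i in range(1, spec.N + 1):
        dev = spec.harmonic_B(i) * np.cos(
            2.0 * np.pi * spec.f_r * t + spec.harmonic_alpha(i)
        ) + pf
        scale = i if spec.order_scaling else 1
        freqs[i - 1] = i * spec.f0 + scale * dev
    return t, freqs


def make_true_pulse(
    spec: TruePulseSpec, fs: float, duration: float, seed: int | None = 0
) -> Waveform:
    """Synthesize the true multi-harmonic pulse y(t).

    Phase is accumulated by trapezoidal integration of the instantaneous
    frequency at the sampling rate; raises if any harmonic would exceed
    a quarter of the sampling rate (comfortably below Nyquist).
    """
    for i in range(1, spec.N + 1):
        if fs <= 4.0 * i * spec.f0:
            raise ValueError(
                f"harmonic {i} at {i * spec.f0:.3g} Hz needs fs > "
                f"{4.0 * i * spec.f0:.3g} Hz (got fs = {fs:g} Hz)"
            )
    t, freqs = true_instant_frequencies(spec, fs, duration, seed)
    y = np.zeros_like(t)
    for i in range(1, spec.N + 1):
        theta = (
            2.0 * np.pi * cumulative_trapezoid(freqs[i - 1], t, initial=0.0)
            + spec.phi0[i - 1]
        )
        y += spec.A[i - 1] * np.cos(theta)
    return Waveform(y, fs)


# ---------------------------------------------------------------------------
# Baseline drift
# ---------------------------------------------------------------------------


def make_baseline_drift(
    sdof: SDOFConfig, fs: float, duration: float, seed: int | None = 0
) -> Waveform:
    """Low-frequency sensor drift: sinusoids plus a band-limited random walk.

    All spectral mass stays below 0.7 Hz; the walk is low-pass filtered
    (zero phase) at ``drift_walk_cutoff`` and scaled to RMS
    ``drift_walk_amp``.  Reproducible from ``seed``.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short")
    t = np.arange(n) / fs
    xb = np.zeros(n)
    for f_hz, amp, phase in sdof.drift_sinusoids:
        xb += amp * np.cos(2.0 * np.pi * f_hz * t + phase)
    if sdof.drift_walk_amp > 0.0:
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.standard_normal(n))
        sos = butter(4, sdof.drift_walk_cutoff, btype="low", fs=fs, output="sos")
        walk = sosfiltfilt(sos, walk)
        walk -= walk.mean()
        rms = math.sqrt(float(np.mean(walk**2)))
        if rms > 0:
            xb += sdof.drift_walk_amp / rms * walk
    return Waveform(xb, fs)


# ---------------------------------------------------------------------------
# SDOF integration
# ---------------------------------------------------------------------------


def _deriv4(y: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central-difference derivative (second-order at edges)."""
    d = np.gradient(y, dt)
    if y.size >= 5:
        d[2:-2] = (y[:-4] - 8.0 * y[1:-3] + 8.0 * y[3:-1] - y[4:]) / (12.0 * dt)
    return d


def _mid4(a: np.ndarray) -> np.ndarray:
    """Cubic-interpolated midpoints a[i+1/2] (length n-1)."""
    mid = 0.5 * (a[:-1] + a[1:])
    if a.size >= 4:
        mid[1:-1] = (9.0 * (a[1:-2] + a[2:-1]) - (a[:-3] + a[3:])) / 16.0
    return mid


def simulate_tcs(y: Waveform, x_b: Waveform, sdof: SDOFConfig) -> Waveform:
    """Integrate the base-excited oscillator with drift-coupled parameters.

    Solves ``m(t) x'' + c(t) x' + k(t) x = k(t) y + c(t) y'`` with a
    fixed-step fourth-order Runge-Kutta scheme at the signal sampling rate.
    The first :data:`TRANSIENT_S` seconds of the output carry the start-up
    transient; callers are expected to discard them (``make_ppg`` does).
    """
    if not y.same_grid(x_b):
        raise ValueError("y and x_b must share sampling rate and length")
    fs = y.fs
    dt = 1.0 / fs
    n = y.n

    xb = x_b.samples / sdof.x_b_scale
    m = sdof.m0 * (1.0 + sdof.gamma_m * xb)
    c = sdof.c0 * (1.0 + sdof.gamma_c * xb)
    k = sdof.k0 * (1.0 + sdof.gamma_k * xb)
    if m.min() <= 0.0 or k.min() <= 0.0:
        raise SimulationError(
            "TVSP coupling drives m(t) or k(t) non-positive; reduce gamma_* "
            "or increase x_b_scale"
        )

    ys = y.samples
    dys = _deriv4(ys, dt)

    # steady-state initial condition at the dominant frequency of y
    rms = math.sqrt(float(np.mean(ys**2)))
    if rms > 0.0:
        spec = np.abs(np.fft.rfft(ys * np.hanning(n)))
        spec[0] = 0.0
        f_dom = np.fft.rfftfreq(n, dt)[int(np.argmax(spec))]
        g0, _ = closed_form_gain(sdof.m0, sdof.c0, sdof.k0, 2.0 * math.pi * f_dom)
    else:
        g0 = 1.0
    x = ys[0] * g0
    v = 0.0

    # midpoint values via 4-point (cubic) interpolation: a linear midpoint
    # would degrade RK4 to second order in the forcing terms
    m_h, c_h, k_h = _mid4(m), _mid4(c), _mid4(k)
    y_h, dy_h = _mid4(ys), _mid4(dys)

    # plain-float lists keep the RK4 loop fast at 125 Hz
    m_l, c_l, k_l = m.tolist(), c.tolist(), k.tolist()
    y_l, dy_l = ys.tolist(), dys.tolist()
    mh_l, ch_l, kh_l = m_h.tolist(), c_h.tolist(), k_h.tolist()
    yh_l, dyh_l = y_h.tolist(), dy_h.tolist()
    out = [0.0] * n
    out[0] = x
    half = 0.5 * dt
    for i in range(n - 1):
        m0_, c0_, k0_, y0_, dy0_ = m_l[i], c_l[i], k_l[i], y_l[i], dy_l[i]
        m1_, c1_, k1_, y1_, dy1_ = m_l[i + 1], c_l[i + 1], k_l[i + 1], y_l[i + 1], dy_l[i + 1]
        mh, ch, kh = mh_l[i], ch_l[i], kh_l[i]
        yh, dyh = yh_l[i], dyh_l[i]

        a1 = (k0_ * (y0_ - x) + c0_ * (dy0_ - v)) / m0_
        x2 = x + half * v
        v2 = v + half * a1
        a2 = (kh * (yh - x2) + ch * (dyh - v2)) / mh
        x3 = x + half * v2
        v3 = v + half * a2
        a3 = (kh * (yh - x3) + ch * (dyh - v3)) / mh
        x4 = x + dt * v3
        v4 = v + dt * a3
        a4 = (k1_ * (y1_ - x4) + c1_ * (dy1_ - v4)) / m1_

        x = x + dt / 6.0 * (v + 2.0 * v2 + 2.0 * v3 + v4)
        v = v + dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        out[i + 1] = x

    xm = np.asarray(out)
    if not np.all(np.isfinite(xm)):
        raise SimulationError("SDOF integration diverged (non-finite state)")
    return Waveform(xm, fs, y.t0)


# ---------------------------------------------------------------------------
# Full record
# ---------------------------------------------------------------------------


def make_ppg(
    spec: TruePulseSpec,
    sdof: SDOFConfig,
    fs: float = 125.0,
    duration: float = 80.0,
    seed: int = 0,
    label: str = "non-AF",
    subject_id: str = "",
) -> SyntheticRecord:
    """Compose a full synthetic PPG record with ground truth.

    The oscillator is integrated over ``duration + TRANSIENT_S`` seconds and
    the transient is discarded, so every returned component shares a common
    steady-state time base of ``duration`` seconds.  ``x_tvsp_true`` is the
    difference between the TVSP-on integration and the same integration with
    all coupling coefficients zero.
    """
    total = duration + TRANSIENT_S
    ss = np.random.SeedSequence(seed)
    s_pulse, s_drift, s_noise = ss.spawn(3)

    y = make_true_pulse(spec, fs, total, s_pulse)
    x_b = make_baseline_drift(sdof, fs, total, s_drift)
    x_m = simulate_tcs(y, x_b, sdof)
    sdof_const = replace(sdof, gamma_m=0.0, gamma_c=0.0, gamma_k=0.0)
    x_c = simulate_tcs(y, x_b, sdof_const)

    rng = np.random.default_rng(s_noise)
    noise = (
        rng.normal(0.0, sdof.noise_sd, y.n) if sdof.noise_sd > 0 else np.zeros(y.n)
    )

    cut = int(round(TRANSIENT_S * fs))

    def _trim(w: np.ndarray) -> Waveform:
        return Waveform(w[cut:].copy(), fs, 0.0)

    ppg = _trim(x_m.samples + x_b.samples + noise)
    return SyntheticRecord(
        ppg=ppg,
        y=_trim(y.samples),
        x_b=_trim(x_b.samples),
        x_m=_trim(x_m.samples),
        x_c=_trim(x_c.samples),
        x_tvsp_true=_trim(x_m.samples - x_c.samples),
        x_noise_true=_trim(noise),
        spec=spec,
        sdof=sdof,
        label=label,
        seed=seed,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------


def nonaf_preset(rng: np.random.Generator) -> tuple[TruePulseSpec, SDOFConfig]:
    """Draw one non-AF subject: small, harmonic-coherent modulation, mild MA."""
    spec = TruePulseSpec(
        f0=rng.uniform(1.0, 1.4),
        N=3,
        A=np.array([1.0, 0.5, 0.25]) * rng.uniform(0.85, 1.15, 3),
        phi0=np.array([0.0, rng.uniform(0.2, 0.5), rng.uniform(0.0, 0.15)]),
        B=rng.uniform(0.02, 0.04),
        f_r=rng.uniform(0.20, 0.30),
        alpha0=rng.uniform(0.0, 2.0 * np.pi),
        pf_sd=0.005,
        pf_corr_time=5.0,
    )
    sdof = SDOFConfig(
        gamma_m=rng.uniform(0.05, 0.12),
        gamma_c=rng.uniform(0.05, 0.12),
        gamma_k=rng.uniform(0.10, 0.25),
        x_b_scale=1.0,
        drift_sinusoids=(
            (rng.uniform(0.06, 0.14), rng.uniform(0.08, 0.15), rng.uniform(0, 2 * np.pi)),
            (rng.uniform(0.22, 0.34), rng.uniform(0.02, 0.05), rng.uniform(0, 2 * np.pi)),
        ),
        drift_walk_amp=0.04,
        noise_sd=0.02,
    )
    return spec, sdof


def af_preset(rng: np.random.Generator) -> tuple[TruePulseSpec, SDOFConfig]:
    """Draw one AF subject: irregular beats, incoherent respiration, large MA.

    Drift amplitude sits between one-third and one-half of the pulse
    amplitude, as observed for AF subjects.
    """
    spec = TruePulseSpec(
        f0=rng.uniform(1.0, 1.5),
        N=3,
        A=np.array([1.0, 0.5, 0.25]) * rng.uniform(0.70, 1.30, 3),
        phi0=np.array([0.0, rng.uniform(-0.2, 0.6), rng.uniform(-0.2, 0.6)]),
        B=rng.uniform(0.05, 0.12),
        f_r=rng.uniform(0.20, 0.35),
        alpha0=rng.uniform(0.0, 2.0 * np.pi),
        pf_sd=rng.uniform(0.08, 0.15),
        pf_corr_time=1.0,  # ~one beat: irregularity is beat-to-beat in AF
        B_jitter=rng.uniform(0.7, 1.4, 3),
        alpha_jitter=rng.uniform(0.0, 2.0 * np.pi, 3),
    )
    sdof = SDOFConfig(
        gamma_m=rng.uniform(0.10, 0.25),
        gamma_c=rng.uniform(0.10, 0.25),
        gamma_k=rng.uniform(0.25, 0.45),
        x_b_scale=1.0,
        drift_sinusoids=(
            (rng.uniform(0.06, 0.14), rng.uniform(0.28, 0.42), rng.uniform(0, 2 * np.pi)),
            (rng.uniform(0.22, 0.34), rng.uniform(0.08, 0.16), rng.uniform(0, 2 * np.pi)),
        ),
        drift_walk_amp=0.10,
        noise_sd=0.04,
    )
    return spec, sdof


def generate_cohort(
    n_af: int,
    n_nonaf: int,
    preset_overrides: dict | None = None,
    seed: int = 0,
    fs: float = 125.0,
    duration: float = 80.0,
) -> list[SyntheticRecord]:
    """Generate a labelled synthetic cohort, reproducible from ``seed``.

    ``preset_overrides`` may contain ``"af_spec"``, ``"af_sdof"``,
    ``"nonaf_spec"`` and/or ``"nonaf_sdof"`` dicts whose entries replace the
    drawn per-subject parameters (applied with :func:`dataclasses.replace`).
    Each record is reproducible from ``(seed, index)`` alone.
    """
    if n_af < 0 or n_nonaf < 0:
        raise ValueError("cohort sizes must be non-negative")
    overrides = preset_overrides or {}
    records: list[SyntheticRecord] = []
    labels = ["AF"] * n_af + ["non-AF"] * n_nonaf
    for idx, label in enumerate(labels):
        rng = np.random.default_rng([seed, idx])
        if label == "AF":
            spec, sdof = af_preset(rng)
            spec = replace(spec, **overrides.get("af_spec", {}))
            sdof = replace(sdof, **overrides.get("af_sdof", {}))
        else:
            spec, sdof = nonaf_preset(rng)
            spec = replace(spec, **overrides.get("nonaf_spec", {}))
            sdof = replace(sdof, **overrides.get("nonaf_sdof", {}))
        rec_seed = int(rng.integers(2**31 - 1))
        records.append(
            make_ppg(
                spec,
                sdof,
                fs=fs,
                duration=duration,
                seed=rec_seed,
                label=label,
                subject_id=f"{label.lower().replace('-', '')}-{idx:02d}",
            )
        )
    return records
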