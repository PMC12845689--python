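# Methods

This note records the model, the estimator conventions, the parameter
choices that matter, and what the synthetic experiments do and do not
demonstrate.

## Signal model

The measured PPG is modelled as the displacement at the mass of a
base-excited single-degree-of-freedom (SDOF) oscillator representing the
tissue–contact–sensor stack, plus additive terms:

```
x_PPG = x_M + x_b + n,    m(t) x_M'' + c(t) x_M' + k(t) x_M = k(t) y + c(t) y'
```

* `y(t) = Σᵢ Aᵢ cos Θᵢ(t)` with `dΘᵢ/dt = 2π·i·(f₀ + Bᵢ cos(2π f_r t + αᵢ) + PF(t))`.
  The harmonic frequency deviation scales with the order `i`: harmonics of
  one fundamental must stay harmonically related, and the extracted
  respiration modulation then grows with order, matching the observed
  order trend.  Order scaling is configurable (`order_scaling`).
* `PF(t)` — the non-harmonic physiological drive — is a stationary
  Ornstein–Uhlenbeck process with SD `pf_sd` (Hz) and correlation time
  `pf_corr_time` (s), exact discretization, shared across harmonics.
* Baseline drift `x_b` is a sum of configured sub-0.7 Hz sinusoids plus a
  random walk low-pass filtered at 0.35 Hz (zero phase) and scaled to a
  requested RMS, so >99% of its spectral power stays below 0.7 Hz.
* TVSP coupling is linear: `k(t) = k₀(1 + γ_k·x_b/x_b_scale)`, likewise
  for `m` and `c`.  Proportional variation of all three parameters cancels
  identically (both sides of the equation scale), so the distortion is
  driven by the *differential* coupling; the presets therefore give the
  stiffness a larger coefficient than the mass and damping, reflecting how
  strongly contact stiffness responds to contact pressure.

### Oscillator parameters

The physical values of `m₀, c₀, k₀` cannot be identified from a single
pulse record; the defaults are simulator conventions chosen so that the
model produces the distortion phenomenology it exists to describe.  The
defaults place the contact natural frequency at **2 Hz with ζ = 0.3**.
Below resonance a base-excited oscillator transmits unity regardless of
`k(t)` (numerator and denominator of the transfer are both ≈ `k`), so a
very stiff contact would make TVSP distortion vanishingly small.  With
the resonance inside the pulse band, harmonics sit at or above it, where
the transmissibility ≈ `k(t)/(m ω²)`: stiffness variation rides
multiplicatively on each harmonic (x_tvsp a few to ~10% of the pulse,
comparable to sensor noise), the amplitude swing dominates, and higher
harmonics come out attenuated — all features of the real signals.

### Integration

Fixed-step 4th-order Runge–Kutta at the signal sampling rate (125 Hz
default), chosen for bit-reproducibility.  Forcing derivatives use
4th-order central differences and RK4 midpoints use cubic interpolation;
with 2nd-order versions the steady-state response missed the closed form
by ~2% at the top of the pulse band, with them the sweep error is < 0.2%
in gain and < 0.003 rad in phase.  The first 5 s carry the start-up
transient and are discarded before any component is exposed.  Initial
condition: `x_M(0) = y(0)·G₀` at the dominant frequency of `y`, `x_M'(0) = 0`.

## Analysis chain and estimator conventions

* **Baseline removal** — zero-phase Butterworth low-pass at 0.7 Hz,
  order 8.  The order is higher than the band-pass order because the
  filter's skirt must die off before the lowest physiological fundamental
  (~1 Hz); at order 4 it still removed 1.3% of a 1.2 Hz pulse, breaking
  the in-band identity and idempotency properties.
* **Fundamental detection** — Welch spectrum (20 s segments), dominant
  peak in 0.7–3.0 Hz, parabolic log-power interpolation; an input whose
  peak is not ≥4× the in-band median power is rejected as
  non-physiological.
* **Harmonic isolation** — zero-phase Butterworth band-pass, order 4,
  half-width 0.40·f₀ around `i·f₀`.  The band is *geometrically* centred
  on `i·f₀` (a Butterworth band-pass has unity gain at its geometric
  centre).  0.40·f₀ passes the first- and second-order respiratory
  sidebands (spacing f_r ≈ 0.2–0.35 Hz) while keeping neighbour-harmonic
  leakage below 0.01% in power; at 0.35·f₀ the clipped second-order
  sidebands alone cost ~2% envelope ripple.  Zero-phase (forward–backward)
  filtering throughout: the method compares instant phases across
  harmonics, so group delay must be null.
* **Instant parameters** — analytic signal via Hilbert transform.
  `A(t) = |z(t)|`; `f(t)` is the unwrapped-phase derivative smoothed by a
  zero-phase low-pass at 0.5 Hz (passes respiratory FM nearly unity,
  suppresses derivative noise; its gain curve is stored with each track
  for optional bias correction).  2 s are trimmed from each end *before*
  smoothing so the smoother's reflection padding sees valid data — this
  matters: smoothing first smears the Hilbert edge transient past any
  fixed trim.
* **Phase split** — `φ₀(t) = Φ(t) − 2π·f_mean·(t−t₀) − 2πk`, the detrended
  phase residual about the segment-mean frequency.  The identities
  `Φ = 2π f_mean (t−t₀) + φ₀ + const` and `x = A cos Φ` hold exactly.
  Note `f(t)` and `φ₀(t)` are deliberately *redundant* views of the same
  phase: both carry the respiratory modulation (as FM and as integrated
  phase respectively).  A reconstruction therefore uses either the
  time-varying `∫f dt` with the constant mean phase `φ̄₀` (x_tf), or the
  constant frequency with `φ̄₀` (x_cf) — never both time-varying at once.
* **Reconstruction anchoring** — the integration constant of each
  harmonic's phase is set by the circular mean of the discrepancy against
  the measured analytic phase, which zeroes the mean phase offset and
  makes the x_tf-vs-x_HVD residual a pure artifact/noise estimate.  (A
  midpoint anchor leaves an arbitrary offset of up to the full respiratory
  phase amplitude and inflates the residual several-fold.)
* **HR conventions** — HRV of any series is its RMS deviation about its
  own temporal mean (the only reference computable from one segment).
  `HR_φᵢ` divides by the harmonic order so all harmonics estimate the same
  physiological HR.  Across-harmonic spread uses the sample (n−1) SD.
* **Respiration** — search band 0.1–0.6 Hz (adult resting breathing),
  2nd-order zero-phase band-pass.  RR is the instantaneous frequency of
  the analytic band signal, smoothed at 0.1 Hz and clipped to the band; RM
  is the analytic envelope times the instantaneous rate, converting the
  phase amplitude `i·B/f_r` rad back to the frequency-deviation amplitude
  `i·B` Hz.  RM is reported per harmonic *without* dividing by order,
  preserving the order trend.  Means are taken after trimming 8 s per
  edge — the 0.1 Hz rate smoother settles over ~1/cutoff, and a shorter
  trim biases the mean RR low by ~0.005 Hz.  Series with band SD below
  1e-3 (rad or Hz) are flagged unreliable.
* **Cycle segmentation** — onsets are local minima preceding the steepest
  upstrokes; the derivative is low-passed at 10 Hz for peak detection
  (the upstroke band ends well below that; unsmoothed derivatives of
  noisy records produce double detections), refractory period 0.4/f₀.
  RMSSD operates on per-cycle HR in bpm by default; an inter-beat-interval
  variant sits behind a flag.
* **Classification** — one cut per index family, majority vote by
  default.  SD(HR) cut 0.073 bpm (geometric mean of the reported group
  extremes 0.23 and 0.023); RMSE(HR_φ) cut 1.9 bpm and RM cut 0.09 Hz
  (geometric means of the analytic boundary values implied by the cohort
  presets' B ranges: 60·B/√2 at B = 0.04/0.05, and 2B at the same
  boundary).  Thresholds are configuration, not learned: the screening
  claim rests on non-overlapping group ranges, not on a trained rule.

## Synthetic cohorts: what they emulate and what they don't

The non-AF preset draws `f₀ ∈ [1.0, 1.4]` Hz, coherent respiration
`B ∈ [0.02, 0.04]` Hz at `f_r ∈ [0.2, 0.3]` Hz, weak physiological noise
(`pf_sd = 0.005` Hz, τ = 5 s), mild drift (~0.15 of the pulse amplitude)
and noise SD 0.02.  The AF preset draws `pf_sd ∈ [0.08, 0.15]` Hz with
τ = 1 s (≈ one beat — the irregularity of AF is beat-to-beat),
`B ∈ [0.05, 0.12]` Hz with independent per-harmonic amplitude jitter
(×0.7–1.4) and phase offsets (harmonic-incoherent respiration), drift
between one-third and one-half of the pulse amplitude, and noise SD 0.04.
Records are 80 s at 125 Hz; every record is reproducible from
(seed, index).

The generator emulates: harmonic structure with respiratory FM, beat-to-
beat irregularity, drift-coupled multiplicative distortion, band-limited
drift, white sensor noise.  It does **not** emulate: beat-morphology
changes (the harmonic amplitudes `Aᵢ` are constant within a record, per
the pulse model), optical transduction, intermittent contact or contact
nonlinearity, non-Gaussian noise, or very low harmonic SNR.  Consequently
a passing synthetic cohort shows that the *estimators* separate the
modelled AF phenotype perfectly; it does not certify performance on real
recordings, where waveform morphology and signal quality vary far more.

One measured consequence: the across-harmonic HR-spread family
(SD(HR)/SD(HR_φ)) separates the groups only when the beat-to-beat
irregularity is large enough to stress the harmonic band-pass tracking
(roughly `pf_sd ≳ 0.1` Hz at these settings).  AF subjects drawn at the
low end of the preset range track cleanly on all three harmonics and fall
into the non-AF SD(HR) range, so that family is not non-overlapping on
the default cohort, while the HRV and RM families are, and the
majority-rule classifier is still 100% accurate.  On real signals the
spread is additionally driven by low harmonic SNR and artifact-induced
phase slips, which the constant-amplitude generator does not produce.

## Effect hierarchy

The multiplicative-artifact effect hierarchy — amplitude swung strongly,
frequency slightly, initial phase barely — is asserted on the fundamental
with relative depths `std(A)/mean(A)`, `std(f)/f_mean`, `std(φ₀)/2π`.
For higher harmonics the order-scaled respiratory phase (amplitude
`i·B/f_r` rad) grows linearly with order while the relative FM depth does
not, so under any slow modulation the frequency-vs-phase ordering is an
algebraic impossibility there; the hierarchy is a statement about the
artifact's action on a harmonic, cleanest on the dominant one.

## Numerical conventions

Segment bounds are inclusive-start/exclusive-end in seconds from record
start.  All conservation identities (`x_PPG = x_M + x_b + n`,
`x₀ = x_HVD + x_noise`, `x_tvsp = x_HVD − x_tf`) hold to floating
round-off by construction and are asserted in the tests.  Degenerate
inputs fail loudly: undamped resonance, non-positive `m(t)`/`k(t)`,
Nyquist violations (named harmonic), flat signals, spectrally peakless
inputs, too-short records.  Weak-envelope tracks (envelope below 1e-3 of
the band RMS for >10% of samples) are flagged rather than dropped.

## Problem sizes

The test suite and the acceptance script use 80 s records at 125 Hz —
the segment length and rate of the screening protocol — with cohorts of
18 + 14 subjects, a 10-frequency oscillator sweep, 3-record round-trip
batches and 4-replicate sweeps per irregularity level; the full
acceptance run completes in under a minute on one CPU.

## Known limitations

* WFDB record I/O is not provided; records travel as `time_s,ppg` CSV
  with JSON sidecars.
* Segment selection is config-driven; `find_quiet_segment` is a
  convenience heuristic, not a signal-quality index.
* The classifier thresholds assume the amplitude scale conventions of the
  presets for families (2) and (3); on other data they are configuration
  to be set from the observed group ranges.
* Respiration extraction assumes a single dominant respiratory component
  in 0.1–0.6 Hz; multi-band or apneic breathing is out of scope.
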