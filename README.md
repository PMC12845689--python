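# ppgtf

Time–frequency analysis of at-rest photoplethysmogram (PPG) signals for
atrial-fibrillation (AF) screening, built on a mechanical model of how
motion artifact enters the measurement.

## The problem

A PPG sensor pressed against the skin reads the arterial pulse through a
stack of tissue, contact interface and sensor mass (the TCS stack).  Even
at rest, small body motion displaces the sensor relative to the artery.
That displacement appears twice in the recorded signal: directly, as
low-frequency (< 0.7 Hz) **baseline drift** `x_b(t)`, and indirectly,
because the drift changes the effective mass, damping and stiffness of the
contact — **time-varying system parameters (TVSP)** — which multiplies a
slow distortion onto every harmonic of the pulse.  Added sensor noise
completes the picture:

```
x_PPG(t) = x_M(t) + x_b(t) + noise,      x_M(t) = x_C(t) + x_tvsp(t)
```

where the TCS stack is a base-excited single-degree-of-freedom oscillator

```
m(t) x_M'' + c(t) x_M' + k(t) x_M = k(t) y + c(t) y',
m(t), c(t), k(t) ∝ x_b(t)
```

driven by the true arterial pulse `y(t) = Σᵢ Aᵢ cos Θᵢ(t)` whose harmonic
frequencies are modulated by respiration (respiratory sinus arrhythmia of
amplitude `B` at rate `f_r`) and by non-harmonic physiological variation.

The package removes `x_b` with a zero-phase low-pass filter, isolates the
first three harmonics with zero-phase band-pass filters, and tracks each
harmonic's **instant amplitude** `Aᵢ(t)`, **instant frequency** `fᵢ(t)`
and **instant initial phase** `φ₀ᵢ(t)` through the Hilbert analytic
signal.  The multiplicative artifact swings `Aᵢ(t)` strongly, perturbs
`fᵢ(t)` slightly, and leaves `φ₀ᵢ(t)` essentially untouched — so an
artifact- and noise-free pulse is rebuilt from the amplitude regression
line and the phase statistics, and the physiological quantities are read
from the tracks:

* `HRᵢ(t) = 60·fᵢ(t)/i` — total heart rate, with HRV = RMSE about its mean;
* `HR_φᵢ(t)` — respiration-only heart rate from the band-passed phase;
* `RR` and `RM` — respiration rate and modulation from the phase residual;
* RMSSD and per-cycle HR from time-domain cycle segmentation.

Three index families separate AF from non-AF subjects: (1) the
across-harmonic spread SD(HR), SD(HR_φ); (2) the per-harmonic HRVs
RMSE(HRᵢ), RMSE(HR_φᵢ); (3) the per-harmonic respiration modulation
mean(B_φᵢ).  A configurable threshold classifier (majority vote by
default) yields the AF / non-AF verdict.

A forward simulator of the same model generates ground-truthed synthetic
records and cohorts (AF subjects: large irregular beat-to-beat frequency
variation, harmonic-incoherent respiration, heavy drift; non-AF subjects:
small coherent modulation), so the whole pipeline is testable end-to-end
without external data.

## Worked example

Write one synthetic AF and one non-AF record (80 s at 125 Hz, CSV with
columns `time_s,ppg` plus a JSON ground-truth sidecar), then analyze them:

```sh
$ ppgtf fixtures --out demo --seed 3
$ ppgtf analyze demo/af.csv
f0: 1.175 Hz   HR: 68.6 bpm
SD(HR): 0.227 bpm   SD(HR_phi): 0.233 bpm
RMSE(HR_i): [6.62 6.56 5.76] bpm
RMSE(HR_phi_i): [5.33 5.4  4.79] bpm
mean(B_phi_i): [0.102 0.198 0.255] Hz
verdict: AF  votes: {'hr_spread': True, 'hrv': True, 'resp_modulation': True}

$ ppgtf analyze demo/nonaf.csv
f0: 1.193 Hz   HR: 71.6 bpm
SD(HR): 0.004 bpm   SD(HR_phi): 0.007 bpm
RMSE(HR_i): [0.92 0.9  0.9 ] bpm
RMSE(HR_phi_i): [0.89 0.86 0.85] bpm
mean(B_phi_i): [0.02  0.041 0.06 ] Hz
verdict: non-AF  votes: {'hr_spread': False, 'hrv': False, 'resp_modulation': False}
```

Reading the numbers: both subjects have ordinary mean heart rates, but the
AF record's irregular rhythm inflates every HRV index by roughly a factor
of five (6.6 vs 0.9 bpm total HRV on the fundamental), spreads the
per-harmonic HR estimates apart (SD(HR) 0.227 vs 0.004 bpm), and raises
the apparent respiration modulation on every harmonic.  Each of the three
index families votes AF for the first record and non-AF for the second.

`ppgtf cohort --n-af 18 --n-nonaf 14 --out results/` runs the batch
experiment and writes per-subject indices, group summaries with
non-overlap flags, and the classification accuracy.  `ppgtf analyze
RECORD.csv --out OUTDIR` additionally writes every intermediate
(`x0`, `x_b`, per-harmonic tracks, `x_tf`, `x_cf`, `x_tvsp`, `x_noise`)
and a provenance log.  Library use starts at
`ppgtf.analyze_waveform(ppgtf.read_record("record.csv")[0])`.

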