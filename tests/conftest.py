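"""Shared fixtures: canonical synthetic records and their analyses.

Expensive artifacts (full cohort, reference records) are session-scoped so
the suite simulates each condition once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import ppgtf as pt
from ppgtf.synthgen import (
    SDOFConfig,
    TRANSIENT_S,
    TruePulseSpec,
    true_instant_frequencies,
)

FS = 125.0


@pytest.fixture(scope="session")
def clean_spec() -> TruePulseSpec:
    """Noiseless 3-harmonic pulse with typical resting respiration."""
    return TruePulseSpec(f0=1.2, B=0.03, f_r=0.25, alpha0=0.7, pf_sd=0.0)


@pytest.fixture(scope="session")
def clean_record(clean_spec):
    """Noiseless, drift-free, TVSP-free record (artifact-free reference)."""
    return pt.make_ppg(clean_spec, SDOFConfig(), fs=FS, duration=80.0, seed=5)


@pytest.fixture(scope="session")
def clean_result(clean_record):
    return pt.analyze_waveform(clean_record.ppg)


@pytest.fixture(scope="session")
def tvsp_record():
    """TVSP-on, drift-on record with respiration but no sensor noise."""
    spec = TruePulseSpec(f0=1.2, B=0.03, f_r=0.25, pf_sd=0.0)
    sdof = SDOFConfig(
        gamma_m=0.1,
        gamma_c=0.1,
        gamma_k=0.5,
        drift_sinusoids=((0.1, 0.35, 0.0), (0.28, 0.12, 1.0)),
        drift_walk_amp=0.08,
    )
    return pt.make_ppg(spec, sdof, fs=FS, duration=80.0, seed=3)


@pytest.fixture(scope="session")
def tvsp_result(tvsp_record):
    return pt.analyze_waveform(tvsp_record.ppg)


@pytest.fixture(scope="session")
def cohort():
    """The default 18 AF + 14 non-AF study cohort at a fixed seed."""
    return pt.generate_cohort(18, 14, seed=7)


@pytest.fixture(scope="session")
def cohort_results(cohort):
    return [
        pt.analyze_waveform(rec.ppg, subject_id=rec.subject_id, label=rec.label)
        for rec in cohort
    ]


def track_truth(track, record):
    """Ground-truth instant parameters for one harmonic of a synthetic record.

    Uses the generator's instantaneous frequencies and the quasi-static
    constant-parameter transfer of the oscillator (|H| and arg H evaluated
    along the true frequency track), which is the true content of the
    drift-free signal the decomposition sees.  Returns (A_true, f_true,
    phi0_true) on the track's time base; phi0_true is mean-removed and uses
    the track's own mean frequency, matching the decomposition's phase
    split convention.
    """
    spec, sdof = record.spec, record.sdof
    i = track.order
    total = record.ppg.n / record.ppg.fs + TRANSIENT_S
    pulse_seed = np.random.SeedSequence(record.seed).spawn(3)[0]
    _t, freqs = true_instant_frequencies(spec, record.ppg.fs, total, pulse_seed)
    k0 = int(round(track.t[0] * record.ppg.fs)) + int(TRANSIENT_S * record.ppg.fs)
    f_gen = freqs[i - 1][k0 : k0 + track.n]
    h = np.array(
        [pt.closed_form_gain(sdof.m0, sdof.c0, sdof.k0, 2 * np.pi * fq) for fq in f_gen]
    )
    a_true = spec.A[i - 1] * h[:, 0]
    theta = (
        2 * np.pi * cumulative_trapezoid(f_gen, dx=1 / record.ppg.fs, initial=0.0)
        + np.unwrap(h[:, 1])
    )
    f_true = np.gradient(theta, 1 / record.ppg.fs) / (2 * np.pi)
    phi0_true = theta - 2 * np.pi * track.f_mean * (track.t - track.t[0])
    phi0_true = phi0_true - phi0_true.mean()
    return a_true, f_true, phi0_true
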