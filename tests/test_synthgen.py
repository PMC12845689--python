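"""Forward-simulator tests: closed-form oracle, pulse synthesis, drift,
oscillator integration, record composition, cohort bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.signal import lti, periodogram, step as lti_step

import ppgtf as pt
from ppgtf.synthgen import (
    SDOFConfig,
    SimulationError,
    TruePulseSpec,
    af_preset,
    closed_form_gain,
    generate_cohort,
    make_baseline_drift,
    make_ppg,
    make_true_pulse,
    nonaf_preset,
    simulate_tcs,
)
from ppgtf.waveform import Waveform

FS = 125.0


# ---------------------------------------------------------------------------
# closed_form_gain
# ---------------------------------------------------------------------------


class TestClosedFormGain:
    def test_static_limit_is_unity(self):
        g, ph = closed_form_gain(1.0, 0.5, 100.0, 0.0)
        assert g == pytest.approx(1.0)
        assert ph == pytest.approx(0.0)

    @given(
        c0=st.floats(0.1, 50.0),
        k0=st.floats(1.0, 1e4),
        w=st.floats(0.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_massless_limit_is_identity(self, c0, k0, w):
        # with m0 = 0 the numerator equals the denominator at any frequency
        g, ph = closed_form_gain(0.0, c0, k0, w)
        assert g == pytest.approx(1.0, rel=1e-12)
        assert ph == pytest.approx(0.0, abs=1e-12)

    def test_matches_complex_arithmetic_oracle(self):
        m0, c0, k0 = 1.0, 0.5, 100.0
        w = 2.0 * math.pi * 1.2
        h = complex(k0, c0 * w) / complex(k0 - m0 * w * w, c0 * w)
        g, ph = closed_form_gain(m0, c0, k0, w)
        assert g == pytest.approx(abs(h), rel=1e-12)
        assert ph == pytest.approx(math.atan2(h.imag, h.real), abs=1e-12)

    def test_undamped_resonance_rejected(self):
        with pytest.raises(SimulationError):
            closed_form_gain(1.0, 0.0, 100.0, math.sqrt(100.0))

    @given(w=st.floats(0.0, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_phase_stays_wrapped(self, w):
        _, ph = closed_form_gain(1.0, 3.0, 158.0, w)
        assert -math.pi < ph <= math.pi


# ---------------------------------------------------------------------------
# make_true_pulse
# ---------------------------------------------------------------------------


class TestTruePulse:
    def test_degenerate_single_harmonic_is_pure_cosine(self):
        spec = TruePulseSpec(f0=1.2, N=1, A=[1.0], phi0=[0.0], B=0.0)
        y = make_true_pulse(spec, FS, 40.0, seed=0)
        t = y.t
        assert np.allclose(y.samples, np.cos(2 * np.pi * 1.2 * t), atol=1e-9)

    def test_zero_crossing_count_matches_integration_oracle(self):
        # cycle count over the record equals the integral of the stated
        # instantaneous frequency, computed by an independent quadrature
        spec = TruePulseSpec(f0=1.2, N=1, A=[1.0], phi0=[0.0], B=0.05, f_r=0.25, alpha0=0.3)
        y = make_true_pulse(spec, FS, 80.0, seed=1)
        s = y.samples
        upward = int(np.sum((s[:-1] < 0) & (s[1:] >= 0)))
        cycles, _ = quad(
            lambda t: 1.2 + 0.05 * np.cos(2 * np.pi * 0.25 * t + 0.3), 0, y.duration
        )
        assert abs(upward - cycles) <= 1.0

    def test_nyquist_violation_names_harmonic(self):
        spec = TruePulseSpec(f0=1.2, N=3)
        with pytest.raises(ValueError, match="harmonic 3"):
            make_true_pulse(spec, 14.0, 10.0, seed=0)

    def test_default_analysis_depth_is_three_harmonics(self):
        assert TruePulseSpec(f0=1.2).N == 3

    def test_seed_determinism(self):
        spec = TruePulseSpec(f0=1.1, B=0.03, pf_sd=0.05)
        a = make_true_pulse(spec, FS, 30.0, seed=4)
        b = make_true_pulse(spec, FS, 30.0, seed=4)
        assert np.array_equal(a.samples, b.samples)


# ---------------------------------------------------------------------------
# make_baseline_drift
# ---------------------------------------------------------------------------


class TestBaselineDrift:
    def test_null_spec_gives_zero(self):
        xb = make_baseline_drift(SDOFConfig(), FS, 30.0, seed=0)
        assert np.all(xb.samples == 0.0)

    def test_sinusoid_band_limited(self):
        sdof = SDOFConfig(drift_sinusoids=((0.1, 1.0, 0.0),))
        xb = make_baseline_drift(sdof, FS, 120.0, seed=0)
        f, p = periodogram(xb.samples, fs=FS)
        assert f[np.argmax(p)] == pytest.approx(0.1, abs=0.02)
        out_of_band = p[f >= 0.7].sum() / p.sum()
        assert out_of_band < 0.01

    def test_random_walk_band_limited_and_scaled(self):
        sdof = SDOFConfig(drift_walk_amp=0.3)
        xb = make_baseline_drift(sdof, FS, 120.0, seed=3)
        rms = np.sqrt(np.mean(xb.samples**2))
        assert rms == pytest.approx(0.3, rel=1e-9)
        f, p = periodogram(xb.samples, fs=FS)
        assert p[f >= 0.7].sum() / p.sum() < 0.01

    def test_drift_frequency_above_band_rejected(self):
        with pytest.raises(ValueError, match="0.7"):
            SDOFConfig(drift_sinusoids=((0.8, 1.0, 0.0),))

    def test_af_preset_drift_amplitude_fraction(self):
        # AF drift amplitude sits between one-third and one-half of the
        # pulse amplitude (peak-to-peak of drift vs pulse signal)
        rng = np.random.default_rng(0)
        for _ in range(5):
            spec, sdof = af_preset(rng)
            amp = sum(a for _f, a, _p in sdof.drift_sinusoids) + sdof.drift_walk_amp
            pulse_amp = float(np.sum(spec.A[: spec.N]))
            assert 0.2 * pulse_amp < amp < 0.6 * pulse_amp


# ---------------------------------------------------------------------------
# simulate_tcs
# ---------------------------------------------------------------------------


class TestSimulateTcs:
    def test_constant_parameter_limit_matches_closed_form(self):
        sdof = SDOFConfig()
        f = 1.7
        spec = TruePulseSpec(f0=f, N=1, A=[1.0], phi0=[0.4], B=0.0)
        y = make_true_pulse(spec, FS, 40.0, seed=0)
        xm = simulate_tcs(y, Waveform(np.zeros(y.n), FS), sdof)
        g0, ph = closed_form_gain(sdof.m0, sdof.c0, sdof.k0, 2 * np.pi * f)
        cut = int(10 * FS)
        ys, xs = y.samples[cut:], xm.samples[cut:]
        g_meas = np.sqrt(np.mean(xs**2) / np.mean(ys**2))
        t = np.arange(xs.size) / FS
        ph_meas = np.angle(
            np.sum(xs * np.exp(-2j * np.pi * f * t))
            / np.sum(ys * np.exp(-2j * np.pi * f * t))
        )
        assert g_meas == pytest.approx(g0, rel=0.01)
        assert ph_meas == pytest.approx(ph, abs=0.02)

    def test_zero_input_gives_zero_output(self):
        n = int(20 * FS)
        y = Waveform(np.zeros(n), FS)
        xb = Waveform(0.2 * np.sin(2 * np.pi * 0.1 * np.arange(n) / FS), FS)
        xm = simulate_tcs(y, xb, SDOFConfig(gamma_k=0.3))
        assert np.allclose(xm.samples, 0.0, atol=1e-12)

    def test_step_response_matches_analytic_oracle(self):
        # settling envelope vs the damped-oscillator step response
        sdof = SDOFConfig()
        n = int(10 * FS)
        y = np.zeros(n)
        y[int(1 * FS):] = 1.0
        xm = simulate_tcs(Waveform(y, FS), Waveform(np.zeros(n), FS), sdof)
        sys = lti([sdof.c0, sdof.k0], [sdof.m0, sdof.c0, sdof.k0])
        tt, ya = lti_step(sys, T=np.linspace(0, 9, 8000))
        ts = np.arange(n) / FS - 1.0
        xa = np.interp(ts, tt, ya)
        xa[ts < 0] = 0.0
        mask = ts > 0.2  # exclude the sampled-step jump neighbourhood
        assert np.max(np.abs(xm.samples[mask] - xa[mask])) < 0.02

    def test_nonpositive_stiffness_raises_instability(self):
        n = int(20 * FS)
        y = Waveform(np.ones(n) * 0.1, FS)
        xb = Waveform(np.full(n, 1.0), FS)
        with pytest.raises(SimulationError, match="non-positive"):
            simulate_tcs(y, xb, SDOFConfig(gamma_k=-1.5))

    def test_mismatched_grids_rejected(self):
        y = Waveform(np.zeros(100), FS)
        xb = Waveform(np.zeros(101), FS)
        with pytest.raises(ValueError):
            simulate_tcs(y, xb, SDOFConfig())


# ---------------------------------------------------------------------------
# make_ppg / generate_cohort
# ---------------------------------------------------------------------------


class TestMakePpg:
    def test_artifact_free_record_collapses_to_filtered_pulse(self):
        spec = TruePulseSpec(f0=1.2, B=0.0, pf_sd=0.0)
        rec = make_ppg(spec, SDOFConfig(), fs=FS, duration=40.0, seed=0)
        assert np.array_equal(rec.ppg.samples, rec.x_m.samples)
        assert np.all(rec.x_tvsp_true.samples == 0.0)
        assert np.all(rec.x_b.samples == 0.0)

    def test_truth_components_sum_exactly(self, tvsp_record):
        rec = tvsp_record
        lhs = rec.ppg.samples - rec.x_b.samples - rec.x_noise_true.samples
        scale = np.max(np.abs(rec.x_m.samples))
        assert np.max(np.abs(lhs - rec.x_m.samples)) < 1e-9 * scale
        assert np.max(
            np.abs(rec.x_m.samples - rec.x_c.samples - rec.x_tvsp_true.samples)
        ) < 1e-9 * scale

    def test_components_share_grid(self, tvsp_record):
        rec = tvsp_record
        for w in (rec.y, rec.x_b, rec.x_m, rec.x_c, rec.x_tvsp_true, rec.x_noise_true):
            assert rec.ppg.same_grid(w)


class TestCohort:
    def test_empty_cohort(self):
        assert generate_cohort(0, 0, seed=1) == []

    def test_counts_and_labels(self):
        recs = generate_cohort(3, 2, seed=42, duration=30.0)
        assert len(recs) == 5
        assert [r.label for r in recs] == ["AF"] * 3 + ["non-AF"] * 2

    def test_same_seed_bit_identical(self):
        a = generate_cohort(1, 1, seed=5, duration=30.0)
        b = generate_cohort(1, 1, seed=5, duration=30.0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.ppg.samples, rb.ppg.samples)

    def test_presets_reflect_af_phenotype(self):
        rng = np.random.default_rng(1)
        af_spec, _ = af_preset(rng)
        non_spec, _ = nonaf_preset(np.random.default_rng(1))
        assert af_spec.pf_sd > 10 * non_spec.pf_sd
        assert af_spec.B > non_spec.B * 0.9
        assert af_spec.B_jitter is not None and non_spec.B_jitter is None
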