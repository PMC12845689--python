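"""HR/HRV extraction from tracks and the time-domain baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppgtf as pt
from ppgtf.cardiometrics import (
    hr_from_frequency,
    hr_from_phase,
    hr_phase_summary,
    hr_summary,
    per_cycle_hr,
    rmssd,
    segment_cycles,
)
from ppgtf.decompose import HarmonicTrack
from ppgtf.synthgen import SDOFConfig, TruePulseSpec, make_ppg, true_instant_frequencies
from ppgtf.waveform import Waveform

FS = 125.0


def _track(order, f=None, phi0=None, f_mean=None, duration=76.0):
    t = np.arange(0.0, duration, 1.0 / FS)
    fv = f(t) if f else np.full_like(t, 1.2 * order)
    pv = phi0(t) if phi0 else np.zeros_like(t)
    fm = f_mean if f_mean is not None else float(np.mean(fv))
    return HarmonicTrack(
        order=order, t=t, A=np.ones_like(t), f=fv, phi0=pv,
        x=np.cos(2 * np.pi * fm * t), phase=2 * np.pi * fm * t + pv,
        fs=FS, f_mean=fm, phase_offset=0.0, trim=0,
    )


class TestHrFromFrequency:
    def test_constant_frequency(self):
        tr = _track(2, f=lambda t: np.full_like(t, 2.4))
        hr, e = hr_from_frequency(tr)
        assert np.allclose(hr, 72.0)
        assert e == 0.0

    def test_sinusoidal_hrv_is_rms_of_sinusoid(self):
        tr = _track(1, f=lambda t: 1.2 + 0.05 * np.cos(2 * np.pi * 0.25 * t))
        _, e = hr_from_frequency(tr)
        assert e == pytest.approx(60 * 0.05 / np.sqrt(2), rel=0.01)

    def test_af_exceeds_nonaf_on_every_harmonic(self, cohort, cohort_results):
        af = [r for rec, r in zip(cohort, cohort_results) if rec.label == "AF"]
        non = [r for rec, r in zip(cohort, cohort_results) if rec.label == "non-AF"]
        for k in range(3):
            assert min(r.indices.rmse_hr[k] for r in af) > max(
                r.indices.rmse_hr[k] for r in non
            )


class TestHrSummary:
    def test_arithmetic(self):
        # per-harmonic mean HRs of 71/72/73 bpm
        tracks = []
        for i, bpm in enumerate((71.0, 72.0, 73.0), start=1):
            tracks.append(_track(i, f=lambda t, b=bpm, o=i: np.full_like(t, b * o / 60)))
        hr, sd = hr_summary(tracks)
        assert hr == pytest.approx(72.0)
        assert sd == pytest.approx(1.0)

    def test_identical_tracks_zero_spread(self):
        tracks = [_track(i, f=lambda t, o=i: np.full_like(t, 1.2 * o)) for i in (1, 2, 3)]
        _, sd = hr_summary(tracks)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_clean_synthetic_harmonics_agree(self, clean_result):
        assert clean_result.cardiac.sd_hr < 0.05


class TestHrFromPhase:
    def test_analytic_fm_identity(self):
        tr = _track(
            1,
            phi0=lambda t: (0.05 / 0.25) * np.sin(2 * np.pi * 0.25 * t),
            f_mean=1.2,
        )
        hr, e = hr_from_phase(tr)
        assert np.mean(hr) == pytest.approx(72.0, abs=0.1)
        assert np.max(hr) == pytest.approx(75.0, abs=0.3)
        assert e == pytest.approx(3.0 / np.sqrt(2), rel=0.03)

    def test_constant_phase(self):
        tr = _track(2, f_mean=2.4)
        hr, e = hr_from_phase(tr)
        assert np.allclose(hr, 72.0)
        assert e == 0.0

    def test_known_modulation_recovered(self, clean_record, clean_result):
        b = clean_record.spec.B
        e = clean_result.cardiac.rmse_hr_phi[0]
        assert e == pytest.approx(60 * b / np.sqrt(2), rel=0.10)

    def test_summary_arithmetic(self):
        tracks = []
        for i, bpm in enumerate((72.0, 72.1, 71.9), start=1):
            tracks.append(_track(i, f_mean=bpm * i / 60))
        hr, sd = hr_phase_summary(tracks)
        assert hr == pytest.approx(72.0, abs=1e-6)
        assert sd == pytest.approx(0.1, abs=1e-6)

    def test_af_phase_spread_exceeds_nonaf(self, cohort, cohort_results):
        # harmonic-incoherent respiration in AF raises the respiration-only
        # HRV on every harmonic relative to non-AF
        af = [r for rec, r in zip(cohort, cohort_results) if rec.label == "AF"]
        non = [r for rec, r in zip(cohort, cohort_results) if rec.label == "non-AF"]
        assert min(np.min(r.indices.rmse_hr_phi) for r in af) > max(
            np.max(r.indices.rmse_hr_phi) for r in non
        )


class TestSegmentCycles:
    def test_pure_cosine_onset_count(self):
        t = np.arange(0.0, 80.0, 1.0 / FS)
        x = Waveform(np.cos(2 * np.pi * 1.2 * t), FS)
        onsets, _ = segment_cycles(x, 1.2)
        assert abs(len(onsets) - 96) <= 1

    def test_beat_intervals_match_generator(self):
        spec = TruePulseSpec(f0=1.2, B=0.03, f_r=0.25, pf_sd=0.005)
        rec = make_ppg(spec, SDOFConfig(), fs=FS, duration=80.0, seed=2)
        res = pt.analyze_waveform(rec.ppg)
        trk = res.decomposition.tracks[0]
        x1 = Waveform(trk.x, FS, trk.t[0])
        onsets, _ = segment_cycles(x1, res.f0_est)
        iv = np.diff(onsets) / FS
        _t, freqs = true_instant_frequencies(
            spec, FS, 85.0, np.random.SeedSequence(2).spawn(3)[0]
        )
        k0 = int(round(x1.t0 * FS)) + int(5 * FS)
        mid = (onsets[:-1] + onsets[1:]) / 2 + k0
        per_true = 1.0 / np.interp(mid / FS, np.arange(freqs[0].size) / FS, freqs[0])
        err_samples = (iv - per_true) * FS
        assert np.sqrt(np.mean(err_samples**2)) < 1.0

    def test_flat_signal_rejected(self):
        x = Waveform(np.zeros(int(30 * FS)), FS)
        with pytest.raises(ValueError, match="flat"):
            segment_cycles(x, 1.2)

    def test_baseline_passes_through_onsets(self):
        t = np.arange(0.0, 40.0, 1.0 / FS)
        x = Waveform(np.cos(2 * np.pi * 1.2 * t) + 0.05 * t, FS)
        onsets, baseline = segment_cycles(x, 1.2)
        assert np.allclose(baseline[onsets], x.samples[onsets])


class TestRmssd:
    def test_constant_series(self):
        assert rmssd(np.full(10, 72.0)) == 0.0

    def test_alternating_series(self):
        assert rmssd(np.array([71.0, 73.0, 71.0, 73.0])) == pytest.approx(2.0)

    @given(st.lists(st.floats(40.0, 180.0), min_size=3, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_formula(self, vals):
        hr = np.asarray(vals)
        oracle = np.sqrt(np.mean((hr[1:] - hr[:-1]) ** 2))
        assert rmssd(hr) == pytest.approx(oracle, abs=1e-12)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            rmssd(np.array([72.0, 73.0]))

    def test_interval_variant(self):
        hr = np.array([60.0, 75.0, 60.0, 75.0])
        iv = 60.0 / hr
        oracle = np.sqrt(np.mean(np.diff(iv) ** 2))
        assert rmssd(hr, on_intervals=True) == pytest.approx(oracle)


class TestTimeDomainAgreement:
    def test_td_hr_matches_tf_hr_on_clean_record(self, clean_result):
        c = clean_result.cardiac
        assert np.mean(c.td_hr["x1"]) == pytest.approx(c.hr, abs=1.0)
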