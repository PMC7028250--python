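"""Respiratory-variation and heart-rate metrics and automated QC."""

import numpy as np
import pytest

from diurnalfmri import (EffectParams, PulsePeaks, compute_rv,
                         detect_pulse_peaks, hr_summary, physio_qc,
                         preprocess_respiration, rv_summary,
                         rv_window_extent_frames, simulate_pulse)
from diurnalfmri.cohort import CohortSpec, simulate_cohort
from diurnalfmri.physio import (ARRHYTHMIA_OUTLIER, FLATLINE_48, RESP_HIGHFREQ,
                                UNDETECTABLE_PEAKS, RVSeries, poincare_sd1)

FS = 400.0


def sine(freq, duration, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestPreprocessRespiration:
    def test_sine_shape_preserved_unit_sd(self):
        x, _ = sine(0.25, 60)
        out = preprocess_respiration(x, FS)
        assert np.std(out) == pytest.approx(1.0, rel=0.02)
        assert np.corrcoef(out, x)[0, 1] > 0.999

    def test_high_frequency_noise_removed(self, rng):
        clean, _ = sine(0.25, 60)
        noisy = clean + rng.normal(0, 1, clean.size) * np.sin(
            2 * np.pi * 50.0 * np.arange(clean.size) / FS)
        out = preprocess_respiration(noisy, FS)
        assert np.corrcoef(out, clean)[0, 1] > 0.99

    def test_constant_channel_errors(self):
        with pytest.raises(ValueError):
            preprocess_respiration(np.ones(int(20 * FS)), FS)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            preprocess_respiration(np.sin(np.arange(100)), FS)


class TestComputeRV:
    def test_window_spans_eight_frames(self):
        assert rv_window_extent_frames(5.76, 0.72) == pytest.approx(8.0, abs=1e-12)

    def test_constant_waveform_zero_rv(self):
        rv = compute_rv(np.full(int(100 * FS), 3.0), FS, 100, 0.72)
        assert np.allclose(rv.values, 0.0)
        assert rv.values.size == 100

    def test_white_noise_rv_near_one(self, rng):
        x = rng.normal(0, 1.0, int(120 * FS))
        rv = compute_rv(x, FS, 150, 0.72)
        interior = rv.values[5:-5]
        assert abs(interior.mean() - 1.0) < 0.02

    def test_shift_invariance_and_sign_equivariance(self, rng):
        x = rng.normal(0, 1, int(60 * FS))
        a = compute_rv(x, FS, 80, 0.72).values
        b = compute_rv(x + 100.0, FS, 80, 0.72).values
        c = compute_rv(-x, FS, 80, 0.72).values
        assert np.allclose(a, b, atol=1e-8)
        assert np.allclose(a, c, atol=1e-10)

    def test_window_too_small_errors(self):
        with pytest.raises(ValueError):
            compute_rv(np.zeros(1000), 10.0, 5, 0.1, window_seconds=0.1)

    def test_waveform_must_span_run(self):
        with pytest.raises(ValueError):
            compute_rv(np.zeros(int(10 * FS)), FS, 100, 0.72)


class TestRVSummary:
    def test_constant_rv(self):
        sd, mean = rv_summary(RVSeries(np.full(20, 0.7), 5.76, 0.72))
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(0.7)

    def test_hand_example(self):
        sd, mean = rv_summary(RVSeries(np.array([1.0, 3.0]), 5.76, 0.72))
        assert sd == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert mean == pytest.approx(2.0, abs=1e-12)

    def test_scaling(self):
        rv1 = RVSeries(np.array([0.5, 1.0, 1.5]), 5.76, 0.72)
        rv2 = RVSeries(2 * rv1.values, 5.76, 0.72)
        assert rv_summary(rv2) == tuple(2 * np.asarray(rv_summary(rv1)))


def _pulse_ctx(**eff_kwargs):
    spec = CohortSpec(n_families=1, family_size_weights=(1.0,), n_frames=300,
                      n_regions=4, n_cortical=4, physio_hz=FS, seed=5)
    effects = EffectParams(seed=5, **eff_kwargs)
    cohort = simulate_cohort(spec, effects)
    return next(cohort.contexts()), effects


class TestPulsePeaks:
    def test_metronomic_pulse_recovers_exact_hr(self):
        ctx, eff = _pulse_ctx(ibi_sd_s=0.0, ibi_subject_sd=0.0, pulse_noise_sd=0.0)
        ctx.ibi_mean_s = 1.0
        x = simulate_pulse(ctx, eff)
        peaks = detect_pulse_peaks(x, FS)
        n_expected = ctx.spec.run_duration_s  # one beat per second
        assert abs(peaks.n_peaks - n_expected) <= 2
        assert np.all(np.abs(peaks.ibis - 1.0) < 0.01)
        hr_mean, hr_sd, hr_rmssd = hr_summary(peaks)
        assert hr_mean == pytest.approx(60.0, abs=0.1)
        assert hr_sd < 0.05 and hr_rmssd < 0.05

    def test_flat_signal_undetectable(self):
        peaks = detect_pulse_peaks(np.zeros(int(30 * FS)), FS)
        assert UNDETECTABLE_PEAKS in peaks.qc_flags
        assert peaks.n_peaks == 0

    def test_hr_from_constructed_peaks(self):
        peaks = PulsePeaks(peak_times=np.array([0.0, 1.0, 1.8, 2.8]),
                           ibis=np.diff([0.0, 1.0, 1.8, 2.8]),
                           hr_at_peak=60.0 / np.diff([0.0, 1.0, 1.8, 2.8]))
        assert np.allclose(peaks.ibis, [1.0, 0.8, 1.0])
        assert np.allclose(peaks.hr_at_peak, [60.0, 75.0, 60.0])
        hr_mean, hr_sd, hr_rmssd = hr_summary(peaks)
        assert hr_mean == pytest.approx(65.0, abs=1e-9)
        assert hr_rmssd == pytest.approx(15.0, abs=1e-9)

    def test_hr_sd_matches_delta_method(self):
        # iid IBIs (ar=0) with SD 0.05 s around 0.9 s: sd(HR) ~ 60 sigma / mu^2
        ctx, eff = _pulse_ctx(ibi_sd_s=0.05, ibi_ar=0.0, ibi_subject_sd=0.0)
        ctx.ibi_mean_s = 0.9
        peaks = detect_pulse_peaks(simulate_pulse(ctx, eff), FS)
        _, hr_sd, _ = hr_summary(peaks)
        pred = 60.0 * 0.05 / 0.9**2
        n = peaks.ibis.size
        se = pred / np.sqrt(2 * (n - 1))
        assert hr_sd > 0
        assert abs(hr_sd - pred) < 3 * se + 0.2  # slack for delta-method curvature

    def test_time_translation_invariance(self):
        times = np.array([0.5, 1.4, 2.5, 3.3, 4.4])
        p1 = PulsePeaks(times, np.diff(times), 60.0 / np.diff(times))
        p2 = PulsePeaks(times + 17.0, np.diff(times), 60.0 / np.diff(times))
        assert hr_summary(p1) == hr_summary(p2)


class TestPhysioQC:
    def test_flatline_48_detected(self):
        ctx, eff = _pulse_ctx()
        x = simulate_pulse(ctx, eff, mode="flatline_48")
        peaks = detect_pulse_peaks(x, FS)
        hr_mean, _, hr_rmssd = hr_summary(peaks)
        assert hr_mean == pytest.approx(48.0, abs=0.1)
        assert hr_rmssd < 0.5
        qc = physio_qc(peaks)
        assert not qc.pulse_pass and FLATLINE_48 in qc.flags

    def test_clean_run_passes(self):
        ctx, eff = _pulse_ctx()
        peaks = detect_pulse_peaks(simulate_pulse(ctx, eff), FS)
        resp, _ = sine(0.25, 60)
        qc = physio_qc(peaks, resp_filtered=preprocess_respiration(resp, FS),
                       sampling_hz=FS)
        assert qc.pulse_pass and qc.resp_pass

    def test_alternating_ibis_fail_poincare(self):
        ctx, eff = _pulse_ctx()
        x = simulate_pulse(ctx, eff, mode="arrhythmia")
        peaks = detect_pulse_peaks(x, FS)
        # alternating 0.6/1.4 s: successive differences +-0.8 -> SD1 ~ 0.57
        assert poincare_sd1(peaks.ibis) > 0.3
        qc = physio_qc(peaks)
        assert not qc.pulse_pass and ARRHYTHMIA_OUTLIER in qc.flags

    def test_high_frequency_respiration_fails(self, rng):
        # strong sustained 1.5 Hz artefact survives the 2 Hz low-pass
        base, _ = sine(0.25, 60)
        artefact, _ = sine(1.5, 60, amp=3.0)
        filtered = preprocess_respiration(base + artefact, FS)
        qc = physio_qc(resp_filtered=filtered, sampling_hz=FS)
        assert not qc.resp_pass and RESP_HIGHFREQ in qc.flags

    def test_verdict_always_returned(self):
        qc = physio_qc()
        assert qc.pulse_pass and qc.resp_pass and qc.flags == set()
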