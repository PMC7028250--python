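"""Synthetic cohort generator: structure, determinism, injected effects."""

import numpy as np
import pandas as pd
import pytest

from diurnalfmri import (CohortSpec, EffectParams, compute_gs, compute_rv,
                         gs_fluctuation, preprocess_respiration, rv_summary,
                         simulate_bold, simulate_cohort, simulate_respiration,
                         true_amplitude)
from diurnalfmri.cohort import replace


class TestManifest:
    def test_single_participant_counts(self):
        spec = CohortSpec(n_families=1, family_size_weights=(1.0,), seed=0)
        cohort = simulate_cohort(spec)
        assert cohort.n_participants == 1
        assert len(cohort.manifest) == 4  # 2 sessions x 2 runs

    def test_same_seed_identical_manifest(self):
        spec = CohortSpec(n_families=5, seed=42)
        eff = EffectParams(seed=42)
        m1 = simulate_cohort(spec, eff).manifest
        m2 = simulate_cohort(spec, eff).manifest
        pd.testing.assert_frame_equal(m1, m2)
        assert m1.to_csv() == m2.to_csv()

    def test_expected_participant_count(self):
        # E[size] = 0.2 + 2*0.5 + 3*0.3 = 2.1 -> 1050 expected participants;
        # per-cohort SD = sqrt(500 * var(size)) = sqrt(500 * 0.49) ~ 15.65
        spec = CohortSpec(n_families=500, family_size_weights=(0.2, 0.5, 0.3),
                          seed=9)
        n = simulate_cohort(spec).n_participants
        assert abs(n - 1050) < 3 * 15.7

    def test_run2_starts_after_run1(self):
        spec = CohortSpec(n_families=3, seed=1)
        m = simulate_cohort(spec).manifest
        wide = m.pivot_table(index=["participant_id", "session"], columns="run",
                             values="scan_hour")
        gaps = wide[2] - wide[1]
        assert np.allclose(gaps, spec.run_duration_h)

    def test_scan_hours_in_range(self):
        spec = CohortSpec(n_families=50, seed=2)
        m = simulate_cohort(spec).manifest
        run1 = m[m["run"] == 1]
        lo, hi = spec.scan_time_range
        assert run1["scan_hour"].between(lo, hi).all()

    def test_invalid_spec_errors(self):
        with pytest.raises(ValueError):
            CohortSpec(n_families=0)
        with pytest.raises(ValueError):
            CohortSpec(family_size_weights=(0.5, 0.2))
        with pytest.raises(ValueError):
            CohortSpec(n_regions=10, n_cortical=11)


class TestAmplitudeModel:
    def test_tod_slope_plugs_into_amplitude(self):
        eff = EffectParams(beta_tod_gs=-0.5, beta_run_gs=0.0, gamma_rv_gs=0.0)
        a_noon = true_amplitude(eff, 12.0, 1, eff.rv_base)
        a_evening = true_amplitude(eff, 20.0, 1, eff.rv_base)
        assert a_noon - a_evening == pytest.approx(4.0, abs=1e-12)

    def test_amplitude_floored_at_zero(self):
        eff = EffectParams(gs_base_amp=1.0, beta_tod_gs=-5.0, gamma_rv_gs=0.0)
        assert true_amplitude(eff, 22.0, 1, eff.rv_base) == 0.0

    def test_negative_slope_yields_negative_sample_correlation(self):
        # ~200 participants, strong planted decline: measured GS fluctuation
        # correlates negatively with scan hour
        spec = CohortSpec(n_families=103, n_frames=120, n_regions=10,
                          n_cortical=9, seed=21)
        eff = EffectParams(seed=21, beta_tod_gs=-1.0, gamma_rv_gs=0.0,
                           beta_tod_rv=0.0, network_block_corr=0.0,
                           noise_sd=3.0, family_re_sd=1.0, subject_amp_sd=2.0,
                           session_amp_sd=0.5, amp_run_sd=0.5)
        cohort = simulate_cohort(spec, eff)
        rows = [(c.scan_hour, gs_fluctuation(compute_gs(simulate_bold(c, eff))))
                for c in cohort.contexts() if c.session == 1 and c.run == 1]
        hours, fluct = map(np.asarray, zip(*rows))
        r = np.corrcoef(hours, fluct)[0, 1]
        assert r < -0.3
        # permutation p: compare against shuffled-hour nulls
        rng = np.random.default_rng(0)
        nulls = [np.corrcoef(rng.permutation(hours), fluct)[0, 1]
                 for _ in range(199)]
        assert np.mean(np.abs(nulls) >= abs(r)) < 0.05


class TestRespirationGenerator:
    def test_no_modulation_rv_constant(self):
        spec = CohortSpec(n_families=1, family_size_weights=(1.0,), n_frames=300,
                          n_regions=4, n_cortical=4, physio_hz=50.0, seed=3)
        eff = EffectParams(seed=3, resp_sigh_rate_per_min=0.0,
                           resp_freq_jitter=0.0)
        ctx = next(simulate_cohort(spec, eff).contexts())
        ctx.true_rv_sd = 0.0  # modulation variance 0, fixed amplitude
        x = simulate_respiration(ctx, eff)
        rv = compute_rv(preprocess_respiration(x, 50.0), 50.0, 300, 0.72)
        inner = rv.values[5:-5]
        assert np.all(np.abs(inner / inner.mean() - 1.0) < 0.05)

    def test_same_seed_identical_waveform(self, tiny_cohort):
        ctx = next(tiny_cohort.contexts())
        a = simulate_respiration(ctx, tiny_cohort.effects)
        b = simulate_respiration(ctx, tiny_cohort.effects)
        assert np.array_equal(a, b)

    def test_negative_rv_slope_recovered_in_measured_rv(self):
        # ~200 participants with beta_tod_rv < 0: measured RV SD declines
        # with scan hour
        spec = CohortSpec(n_families=103, n_frames=150, n_regions=4,
                          n_cortical=4, physio_hz=40.0, seed=13)
        eff = EffectParams(seed=13, beta_tod_rv=-0.015,
                           resp_sigh_rate_per_min=0.0)
        cohort = simulate_cohort(spec, eff)
        rows = []
        for ctx in cohort.contexts():
            if ctx.session != 1 or ctx.run != 1:
                continue
            x = preprocess_respiration(simulate_respiration(ctx, eff), 40.0)
            sd, _ = rv_summary(compute_rv(x, 40.0, 150, 0.72))
            rows.append((ctx.scan_hour, sd))
        hours, sds = map(np.asarray, zip(*rows))
        assert np.corrcoef(hours, sds)[0, 1] < -0.2


class TestBoldGenerator:
    def test_same_seed_identical_bold(self, tiny_cohort):
        ctx = next(tiny_cohort.contexts())
        a = simulate_bold(ctx, tiny_cohort.effects)
        b = simulate_bold(ctx, tiny_cohort.effects)
        assert np.array_equal(a.data, b.data)

    def test_too_few_frames_errors(self):
        with pytest.raises(ValueError):
            CohortSpec(n_families=1, n_frames=1)

    def test_network_block_correlation_level(self):
        spec = CohortSpec(n_families=1, family_size_weights=(1.0,), n_frames=800,
                          n_regions=34, n_cortical=34, seed=8)
        eff = EffectParams(seed=8, network_block_corr=0.5, gs_base_amp=0.0,
                           beta_run_gs=0.0, gamma_rv_gs=0.0, family_re_sd=0.0,
                           subject_amp_sd=0.0, amp_run_sd=0.0,
                           noise_burst_rate=0.0)
        ctx = next(simulate_cohort(spec, eff).contexts())
        bold = simulate_bold(ctx, eff)
        labels = np.asarray(bold.network_labels)
        corr = np.corrcoef(bold.data, rowvar=False)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = corr[same].mean()
        between = corr[~same & ~np.eye(34, dtype=bool)].mean()
        assert within == pytest.approx(0.5, abs=0.1)
        assert abs(between) < 0.1

    def test_calibration_hits_target_correlation(self):
        from diurnalfmri import calibrate_tod_slope
        spec = CohortSpec(n_families=160, n_frames=200, n_regions=16,
                          n_cortical=15, seed=31)
        eff = EffectParams(seed=31, gamma_rv_gs=0.0, beta_tod_rv=0.0,
                           network_block_corr=0.0, noise_sd=3.0)
        eff = replace(eff, beta_tod_gs=calibrate_tod_slope(spec, eff, -0.3))
        cohort = simulate_cohort(spec, eff)
        sess = (cohort.manifest[cohort.manifest["session"] == 1]
                .groupby("participant_id")[["true_amp", "scan_hour"]].mean())
        r = np.corrcoef(sess["true_amp"], sess["scan_hour"])[0, 1]
        # ~312 participants: sampling SD of r is about 0.052
        assert r == pytest.approx(-0.3, abs=0.16)
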