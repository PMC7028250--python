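"""Respiratory and cardiac metrics with automated quality control.

Simulates physiological logs for one run, derives the RV series and the
heart-rate summaries, then shows the QC screen catching two artefact
modes: the metronomic 48.0-bpm flatline and an alternating-interval
arrhythmia.
"""

from diurnalfmri import (CohortSpec, EffectParams, compute_rv,
                         detect_pulse_peaks, hr_summary, physio_qc,
                         preprocess_respiration, rv_summary, simulate_cohort,
                         simulate_pulse, simulate_respiration)

spec = CohortSpec(n_families=1, family_size_weights=(1.0,), n_frames=300,
                  n_regions=8, n_cortical=8, physio_hz=400.0, seed=11)
effects = EffectParams(seed=11)
ctx = next(simulate_cohort(spec, effects).contexts())

resp = preprocess_respiration(simulate_respiration(ctx, effects), 400.0)
rv = compute_rv(resp, 400.0, spec.n_frames, spec.tr_seconds)
rv_sd, rv_mean = rv_summary(rv)
print(f"RV series: {rv.values.size} frames (one per fMRI frame); "
      f"RV SD = {rv_sd:.3f}, RV mean = {rv_mean:.3f} (z-units)")
print(f"latent RV SD target was {ctx.true_rv_sd:.3f}")

for mode in ("normal", "flatline_48", "arrhythmia"):
    peaks = detect_pulse_peaks(simulate_pulse(ctx, effects, mode=mode), 400.0)
    hr_mean, hr_sd, hr_rmssd = hr_summary(peaks)
    qc = physio_qc(peaks)
    verdict = "pass" if qc.pulse_pass else f"FAIL {sorted(qc.flags)}"
    print(f"{mode:12s}: HR {hr_mean:6.1f} bpm, SD {hr_sd:5.2f}, "
          f"RMSSD {hr_rmssd:5.2f}  -> QC {verdict}")

print("\nThe flatline mode reproduces a hardware artefact (exactly 48.0 bpm")
print("with near-zero variability); the arrhythmia mode alternates 0.6/1.4 s")
print("interbeat intervals and is caught by its Poincare dispersion.")
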