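# Methods

`diurnalfmri` re-implements, as a tested library, a diurnal-variation
analysis of resting-state fMRI: how the brain's global signal (GS)
fluctuation, physiological and motion summary metrics, regional BOLD
fluctuation, and functional connectivity vary with the clock time of the
scan, with inference that respects the family structure of a twin/sibling
cohort.  Because the source data class (a large restricted-access
connectome study) cannot ship with a package, every analysis stage is
driven by a synthetic-cohort generator with known injected effects; the
generator is first-class, tested code, and its defaults define the study
conditions the analyses are evaluated under.

## The synthetic cohort

**Structure.** A cohort is a set of families whose sizes are drawn from a
weight vector over 1–3 members (default 0.30/0.45/0.25, echoing a
twin-and-sibling registry).  Each participant is scanned in two sessions
(different days) of two consecutive runs; each run acquires `n_frames`
frames at TR = 0.72 s (default 1200 frames = 14.4 min).  The first run's
start time is drawn from a truncated normal over clock hours [8, 22]
(mean 12.5, SD 2.75 h) — matching a scan-time distribution dense around
12:30 — and run 2 starts when run 1 ends.

**BOLD model.** Region `r` at frame `t` is

    x[t, r] = 10000 + g(t) + b_k(r) u_k(t) + eps[t, r]

with all regions loading equally on a smooth shared process `g` (Gaussian
process, ~5 s correlation length, normalised to exact sample SD so the
injected amplitude is the run's GS fluctuation by construction), one
shared process per network `k` whose weight `b_k` is sized to reach a
target within-network correlation `c` via `b = sigma sqrt(c / (1 - c))`,
and white region noise of SD `noise_sd`, with rare "burst" frames
(noise multiplied by `noise_burst_gain`) standing in for scanner/motion
artefacts.  The white-noise component doubles as the run's
unstructured-noise table for the DVARS-dips metric, since the upstream
decomposition that would produce it in real data (ICA component
regression) is out of scope.

**Amplitude model.** The latent GS amplitude of a run is

    A = gs_base_amp + beta_tod_gs (h - 12) + beta_run_gs 1[run 2]
        + gamma_rv_gs (rv - rv_base) + u_family + u_subject
        + u_session + u_run,                        A floored at 0,

with `h` the scan start hour.  The time-of-day effect is linear in the
hour and centred at noon (the empirical decline is linear and not driven
by any particular time of day); the family intercept creates the
non-exchangeability that the permutation scheme must respect; the
session intercept models day-to-day state (arousal, sleep history) shared
by a session's two runs; the run intercept is within-session noise.
Coupling to respiratory variation is centred at `rv_base` so
`gs_base_amp` remains the noon/baseline amplitude.

**Default effect sizes.** Defaults are derived once from the reported
effect structure of the phenomenon (GS fluctuation falling from ~0.22% to
~0.17% of mean signal across a 12-hour scanning day; between-participant
GS–ToD r near −0.17 and within-participant r near −0.20; RV SD–ToD r near
−0.12; RV SD–GS r near +0.55; run-2 paired t in the low teens at N≈900).
With scan-hour SD σ_h ≈ 2.47 h the identities

    total ToD slope  = (0.22% − 0.17%) x 100 / 12 h  ≈ −0.42 BOLD units/h
    r(GS, h)         = slope σ_h / σ_between
    r(RV SD, GS)     = gamma σ_rv,subj / σ_between
    t(run effect)    = beta_run sqrt(N) / (sqrt(2) σ_run-level)

give the shipped defaults: `beta_tod_gs = −0.25` direct plus
`gamma_rv_gs x beta_tod_rv = 40 x (−0.0042) ≈ −0.17` indirect;
`family_re_sd = 2.5`, `subject_amp_sd = 2.0`, `session_amp_sd = 4.0`,
`amp_run_sd = 1.0` (σ_between ≈ 6.1); `rv_subject_sd = 0.08`.  A helper,
`calibrate_tod_slope`, inverts the same variance decomposition to plant an
exact population between-participant correlation for recovery
experiments.

**Respiration.** The waveform is a ~0.25 Hz quasi-sinusoid with a slowly
varying amplitude envelope `1 + m s(t)` (`s` smooth, unit SD, ~15 s
timescale).  Because preprocessing z-scores each run, only the *relative*
modulation depth survives, and `m = rv / sqrt(1 − rv²)` makes the
windowed-SD series hit the run's RV SD target in z-units exactly (verified
to slope ≈ 0.97 against the latent target).  Breathing-rate jitter (~5%)
and sighs — Gaussian bumps of 3x the envelope, ~2 s wide, 1/min at
baseline — add realism; sighing is itself a facet of dynamic breathing, so
the sigh rate scales with the run's RV level rather than acting as
independent measurement noise.  Slow modulations are generated on a 4 Hz
grid and interpolated to the physio sampling rate.

**Pulse.** Beats arrive at interbeat intervals from a positive AR(1)
process (participant-level mean ≈ 0.9 s, SD 0.05 s, lag-1 0.7); the
waveform is a train of 50 ms Gaussian systolic peaks plus sensor noise.
Two artefact modes reproduce known failure cases: a metronomic
48.0-bpm flatline and an alternating 0.6/1.4 s arrhythmia.

**Motion.** Six columns (translations mm, rotations rad) as smooth
low-amplitude drift plus Poisson-count single-frame spikes.

**What the generator does not emulate.** No voxel/grayordinate level, no
surface geometry, no spatially structured artefact topographies, no
realistic cardiac waveform morphology, no heteroscedastic scan-time
densities beyond the truncated normal.  Passing tests therefore
demonstrate correctness of the analysis logic and calibration of the
inference under known dependence — not that real data satisfy the
generative assumptions.

## Metrics

* **GS / GS fluctuation** — unweighted mean over cortical parcels
  (whole-brain variant available); fluctuation is the sample SD (N−1)
  over frames.  Sample SD is used everywhere; the denominator choice is
  immaterial at 1200 frames but is applied consistently.  Percent signal
  change divides by the grand mean 10,000 and multiplies by 100.
* **RV** — the respiration channel is z-scored and low-pass filtered at
  2 Hz (4th-order Butterworth, zero-phase); RV is the windowed sample SD
  in 5.76 s windows (eight frames at TR 0.72 s) centred on each frame's
  acquisition midpoint `(i + 0.5) TR`, truncated at run boundaries so the
  series keeps length `n_frames`.  RV SD/mean summarise the series.  RV is
  computed from the filtered waveform (a raw-waveform switch exists).
* **HR** — peaks are detected on the 10 Hz-low-passed pulse wave
  (minimum spacing 0.25 s, prominence adaptive to the amplitude range),
  refined by parabolic interpolation; HR at each peak is 60 divided by the
  preceding interbeat interval; summaries are mean, sample SD, and RMSSD
  of the HR series.
* **FD / AD** — Power-style sum of absolute backward differences /
  positions, rotations converted to arc length on a 50 mm sphere; an
  RMS-of-derivatives variant sits behind a flag because the phrase
  "summed root-mean-square" is realised differently across tools.  AD is
  computed on the parameters as given (realignment-target reference; a
  first-frame switch exists).  First-frame FD and DVARS are 0.
* **DVARS** — RMS over regions of the frame-differenced signal; computed
  over parcels, so the conventional threshold of 75 applies only on
  grand-mean-10,000 data and is config-exposed.
* **Censoring** — frames with FD > 0.2 mm or DVARS > 75 are outliers,
  plus one frame before and two after, plus any surviving segment
  shorter than five frames.  A session is dropped when either run
  exceeds 50% outliers (strict inequality).
* **DVARS dips** — percent of frames whose unstructured-noise DVARS
  deviates from the run median by at least 75; two-sided, since both dips
  and peaks are anomalies.
* **QC** — automated proxies for the study's visual screening: the
  flatline fails on |HR − 48.0| < 0.2 bpm with RMSSD < 0.5 bpm; arrhythmia
  on Poincaré SD1 (dispersion of successive IBI pairs perpendicular to the
  identity) above 0.1 s, or more than two out-of-range (0.3–2.0 s)
  intervals after deleting isolated ones; respiration on more than 30% of
  post-filter power above 1 Hz.  All thresholds are configuration, not
  claims about the original screening.  A participant contributes a
  session's respiratory (cardiac) metrics only if both runs pass that
  domain's QC.

## Inference

Families are exchangeability blocks: members of a family may be permuted
among themselves, and whole families of equal size may be swapped; draws
compose both moves.  p-values use the add-one estimator
`(1 + #{|null| ≥ |obs|}) / (1 + n_perm)`.  Between-participant tests
correlate session-averaged metric and scan hour; within-participant tests
correlate session-2 minus session-1 deltas, with a null that additionally
sign-flips each family's deltas (session order is exchangeable under the
null).  The paired run test uses family sign-flips of the run-2 − run-1
differences.  BH-FDR is implemented directly (and oracle-tested against a
brute-force step-up and statsmodels).  The NBS screens edges at a
parametric p < 0.001 (t-approximation of the Pearson r — the r-threshold
equivalent is computed once per sample size), scores connected components
by edge count ("extent"; an intensity variant exists), and compares them
to the permutation null of the maximum component statistic; component
p-values then pass through BH-FDR (classical FWER-only reporting is a
switch).  Twin-zygosity subtleties are ignored: all members of a family
are treated as mutually exchangeable.  Robust (Huber, tuning constant
1.345) and median-quantile line fits accompany OLS as heteroscedasticity
controls, via statsmodels.

## Numerical and design choices

* Session-level time of day is the mean of the two run start times;
  run-level analyses use the run start.
* Run matrices are averaged on r within sessions (a Fisher-z switch
  exists); network-block averages exclude the unit diagonal; matrix
  summaries report the median absolute Fisher z over the lower triangle.
* GSR regresses each region on an intercept plus the cortical GS.  When
  the GS of already-residualised data is numerically indistinguishable
  from zero (relative SD < 1e−10), only the intercept is removed, making
  the operation exactly idempotent.
* Degenerate inputs raise: zero-variance regions (named), constant
  covariates, fewer than 4 participants, windows under two samples.
* Generators are pure functions of (spec, effects, seed); every stream is
  keyed by participant/session/run indices so cohorts are reproducible
  under subsetting.

## Problem sizes in tests and the acceptance script

The default spec (1200 frames, 419 regions of which 400 cortical, 400 Hz
physio) states the emulated acquisition.  The test-suite and
`scripts/acceptance.py` run scaled versions — typically 200–300 frames,
12–180 regions, 40–50 Hz physio, cohorts of ~80 to ~1500 participants,
199–4999 permutations, and 200–500 replicates for calibration — chosen so
each experiment isolates the property under test at comfortable power.
Calibration experiments (type-I error, parameter recovery, NBS error
control) pin the variance components they do not study; the NBS power and
GSR-attenuation experiments zero the unrelated amplitude paths so the
planted effect is the only signal.  The mediation experiment uses ~1500
participants because its "residual correlation within ±0.05 of zero"
check is only informative when the null sampling SD of r (≈ 1/sqrt(N)) is
well below the band, and disables sighs so measured RV SD is a faithful
proxy of the latent respiratory state being manipulated.

## Known limitations

* The GS shared process has exact sample SD, so SD-estimation noise is
  absent; run-to-run variability is injected explicitly instead.  Real
  data mix both sources.
* DVARS on parcels is smoother than voxelwise DVARS; with the default
  generator, DVARS-driven censoring is rare and outlier % is dominated by
  FD.
* The automated physiological QC encodes the two artefact families the
  generator can produce; real recordings fail in more ways.
* Network assignment is a contiguous partition of the cortical regions
  into the 17 canonical large-scale networks (plus one subcortical
  block), not an empirical parcellation.
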