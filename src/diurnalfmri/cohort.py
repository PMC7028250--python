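"""Synthetic HCP-like cohorts with controllable time-of-day effects.

The generator emulates the structure of a large twin/sibling resting-state
fMRI study: families of 1-3 participants, two sessions of two back-to-back
runs, scan start times drawn from a distribution over clock hours peaked
near 12:30, parcellated BOLD on the grand-mean-10,000 scale, respiratory
and pulse waveforms, and 6-parameter motion traces.

The data-generating model for one run's BOLD is

    x[t, r] = 10000 + g(t) + b_k(r) * u_k(t) + eps[t, r]

where ``g`` is a smooth shared ("global") process whose amplitude

    A = gs_base_amp + beta_tod_gs * (hour - 12) + beta_run_gs * 1[run 2]
        + gamma_rv_gs * (rv_sd - rv_base) + family effect + subject effect

is floored at 0, ``u_k`` are per-network shared processes sized to hit a
target within-network correlation, and ``eps`` is white region noise with
occasional burst frames (artefact analogue).  Every generator is a pure
function of (spec, effects, seed), so ground truth is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .physio import PhysioTrace
from .signals import ParcellatedBOLD

__all__ = [
    "NETWORKS_17",
    "CohortSpec",
    "EffectParams",
    "RunContext",
    "Cohort",
    "GroundTruth",
    "default_network_labels",
    "simulate_cohort",
    "simulate_bold",
    "simulate_respiration",
    "simulate_pulse",
    "simulate_physio",
    "simulate_motion",
    "true_amplitude",
    "scan_hour_sd",
    "calibrate_tod_slope",
]

#: the 17 large-scale cortical networks plus one subcortical block
NETWORKS_17 = [
    "VisCent", "VisPeri", "SomMotA", "SomMotB", "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB", "LimbicA", "LimbicB", "ContA", "ContB",
    "ContC", "DefaultA", "DefaultB", "DefaultC", "TempPar",
]
SUBCORTEX = "Subcortex"


@dataclass
class CohortSpec:
    """Structural description of a simulated cohort.

    Defaults mirror the source study's acquisition: 1,200 frames at
    TR = 0.72 s per run, two sessions of two consecutive runs, physiological
    logs at 400 Hz, 419 regions of which 400 are cortical, and scan start
    times on [8, 22] clock hours peaked near 12.5.
    """

    n_families: int = 100
    family_size_weights: tuple[float, ...] = (0.3, 0.45, 0.25)
    sessions: int = 2
    runs_per_session: int = 2
    n_frames: int = 1200
    tr_seconds: float = 0.72
    physio_hz: float = 400.0
    n_regions: int = 419
    n_cortical: int = 400
    scan_time_mean: float = 12.5
    scan_time_sd: float = 2.75
    scan_time_range: tuple[float, float] = (8.0, 22.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.sessions <= 0 or self.runs_per_session <= 0:
            raise ValueError("counts must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.tr_seconds <= 0 or self.physio_hz <= 0:
            raise ValueError("tr_seconds and physio_hz must be positive")
        if self.n_cortical > self.n_regions or self.n_cortical < 1:
            raise ValueError("need 1 <= n_cortical <= n_regions")
        w = np.asarray(self.family_size_weights, dtype=float)
        if w.ndim != 1 or w.size == 0 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("family_size_weights must be non-negative and sum to 1")

    @property
    def run_duration_s(self) -> float:
        return self.n_frames * self.tr_seconds

    @property
    def run_duration_h(self) -> float:
        return self.run_duration_s / 3600.0


@dataclass
class EffectParams:
    """Injected effect sizes and noise scales.

    Units: BOLD amplitudes are on the grand-mean-10,000 scale; time-of-day
    slopes are per clock hour centred at 12:00; RV quantities are in
    z-units of the filtered respiratory waveform.  Defaults are sized so a
    large cohort reproduces the reported effect structure (a GS fluctuation
    decline of about 0.22% -> 0.17% of mean signal across the scanning day,
    between-participant GS-ToD r near -0.17, RV SD-ToD r near -0.12 and
    RV SD-GS r near +0.55); see docs/methods.md for the derivations.
    """

    gs_base_amp: float = 20.0
    beta_tod_gs: float = -0.25
    beta_run_gs: float = 1.0
    beta_tod_rv: float = -0.0042
    gamma_rv_gs: float = 40.0
    network_block_corr: float = 0.3
    noise_sd: float = 30.0
    family_re_sd: float = 2.5
    subject_amp_sd: float = 2.0
    session_amp_sd: float = 4.0
    amp_run_sd: float = 1.0
    rv_base: float = 0.2
    rv_subject_sd: float = 0.08
    rv_run_sd: float = 0.03
    motion_spike_rate: float = 3.0
    motion_spike_mm: float = 0.3
    motion_drift_mm: float = 0.04
    noise_burst_rate: float = 2.0
    noise_burst_gain: float = 4.0
    ibi_mean_s: float = 0.9
    ibi_subject_sd: float = 0.08
    ibi_sd_s: float = 0.05
    ibi_ar: float = 0.7
    pulse_noise_sd: float = 0.02
    resp_freq_hz: float = 0.25
    resp_freq_jitter: float = 0.05
    resp_sigh_rate_per_min: float = 1.0
    flatline_fraction: float = 0.0
    arrhythmia_fraction: float = 0.0
    network_tod_slopes: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gs_base_amp < 0:
            raise ValueError("gs_base_amp must be >= 0")
        if not (0.0 <= self.network_block_corr < 1.0):
            raise ValueError("network_block_corr must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class RunContext:
    """Everything one run's generators need: identity, timing, latent truth."""

    participant_id: str
    family_id: str
    p_idx: int
    session: int
    run: int
    scan_hour: float
    true_amp: float
    true_rv_sd: float
    ibi_mean_s: float
    pulse_mode: Literal["normal", "flatline_48", "arrhythmia"]
    spec: CohortSpec


@dataclass
class GroundTruth:
    """Recorded latent quantities of a simulated cohort."""

    runs: pd.DataFrame          # per-run scan_hour, true_amp, true_rv_sd, pulse_mode
    participants: pd.DataFrame  # family assignment and per-participant effects
    slopes: dict                # the injected beta/gamma values


@dataclass
class Cohort:
    """A simulated cohort: manifest plus latent ground truth."""

    spec: CohortSpec
    effects: EffectParams
    participants: pd.DataFrame
    manifest: pd.DataFrame

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def ground_truth(self) -> GroundTruth:
        e = self.effects
        return GroundTruth(
            runs=self.manifest.copy(),
            participants=self.participants.copy(),
            slopes={"beta_tod_gs": e.beta_tod_gs, "beta_tod_rv": e.beta_tod_rv,
                    "beta_run_gs": e.beta_run_gs, "gamma_rv_gs": e.gamma_rv_gs},
        )

    def contexts(self) -> Iterator[RunContext]:
        """Yield one :class:`RunContext` per manifest row."""
        ibi_by_pid = dict(zip(self.participants["participant_id"],
                              self.participants["ibi_mean_s"]))
        for row in self.manifest.itertuples(index=False):
            yield RunContext(
                participant_id=row.participant_id, family_id=row.family_id,
                p_idx=int(row.p_idx), session=int(row.session), run=int(row.run),
                scan_hour=float(row.scan_hour), true_amp=float(row.true_amp),
                true_rv_sd=float(row.true_rv_sd),
                ibi_mean_s=float(ibi_by_pid[row.participant_id]),
                pulse_mode=str(row.pulse_mode), spec=self.spec,
            )


# ---------------------------------------------------------------------------
# helpers

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, *key)))


def _smooth_unit(rng: np.random.Generator, n: int, dt: float,
                 tau_s: float, size: int = 1) -> np.ndarray:
    """Columns of smooth noise with exact sample mean 0 and sample SD (N-1) 1."""
    w = rng.standard_normal((n, size))
    if tau_s > 0 and n > 2:
        w = gaussian_filter1d(w, sigma=max(tau_s / dt, 1e-6), axis=0, mode="reflect")
    w = w - w.mean(axis=0)
    sd = w.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return w / sd


def default_network_labels(n_regions: int, n_cortical: int) -> tuple[list[str], np.ndarray]:
    """Assign cortical regions to the 17 networks in contiguous blocks and
    the remainder to the subcortical block.  Returns (labels, cortical_mask)."""
    edges = np.linspace(0, n_cortical, len(NETWORKS_17) + 1).round().astype(int)
    labels: list[str] = []
    for k, name in enumerate(NETWORKS_17):
        labels.extend([name] * (edges[k + 1] - edges[k]))
    labels.extend([SUBCORTEX] * (n_regions - n_cortical))
    mask = np.zeros(n_regions, dtype=bool)
    mask[:n_cortical] = True
    return labels, mask


def scan_hour_sd(spec: CohortSpec) -> float:
    """SD of the scan-start-hour distribution (truncated normal)."""
    lo, hi = spec.scan_time_range
    a = (lo - spec.scan_time_mean) / spec.scan_time_sd
    b = (hi - spec.scan_time_mean) / spec.scan_time_sd
    return float(truncnorm.std(a, b, loc=spec.scan_time_mean, scale=spec.scan_time_sd))


def _sample_scan_hours(rng: np.random.Generator, spec: CohortSpec, n: int) -> np.ndarray:
    lo, hi = spec.scan_time_range
    a = (lo - spec.scan_time_mean) / spec.scan_time_sd
    b = (hi - spec.scan_time_mean) / spec.scan_time_sd
    return truncnorm.rvs(a, b, loc=spec.scan_time_mean, scale=spec.scan_time_sd,
                         size=n, random_state=rng)


def true_amplitude(effects: EffectParams, scan_hour: float, run: int,
                   rv_sd: float, family_effect: float = 0.0,
                   subject_effect: float = 0.0) -> float:
    """Latent GS amplitude for one run (floored at 0)."""
    amp = (effects.gs_base_amp
           + effects.beta_tod_gs * (scan_hour - 12.0)
           + effects.beta_run_gs * (1.0 if run == 2 else 0.0)
           + effects.gamma_rv_gs * (rv_sd - effects.rv_base)
           + family_effect + subject_effect)
    return max(amp, 0.0)


# ---------------------------------------------------------------------------
# cohort-level simulation

def simulate_cohort(spec: CohortSpec, effects: EffectParams | None = None) -> Cohort:
    """Draw the cohort manifest and all run-level latent quantities.

    Families receive sizes from ``family_size_weights``; each participant is
    scanned in ``spec.sessions`` sessions of ``spec.runs_per_session``
    consecutive runs, with the first run's start time drawn from the scan
    time distribution and later runs starting back-to-back.  Identical
    (spec, effects) including seeds reproduce the manifest exactly.
    """
    effects = effects if effects is not None else EffectParams()
    rng_struct = _rng(spec.seed, 100)
    sizes = rng_struct.choice(
        np.arange(1, len(spec.family_size_weights) + 1),
        p=np.asarray(spec.family_size_weights, float), size=spec.n_families,
    )

    part_rows = []
    p_idx = 0
    for f_idx, size in enumerate(sizes):
        fam_id = f"fam{f_idx + 1:04d}"
        fam_eff = float(_rng(effects.seed, 200, f_idx).normal(0.0, effects.family_re_sd))
        for _ in range(int(size)):
            rng_p = _rng(effects.seed, 300, p_idx)
            part_rows.append({
                "participant_id": f"sub{p_idx + 1:05d}",
                "family_id": fam_id,
                "p_idx": p_idx,
                "family_effect": fam_eff,
                "subject_effect": float(rng_p.normal(0.0, effects.subject_amp_sd)),
                "rv_subject": float(rng_p.normal(0.0, effects.rv_subject_sd)),
                "ibi_mean_s": float(rng_p.normal(effects.ibi_mean_s,
                                                 effects.ibi_subject_sd)),
            })
            p_idx += 1
    participants = pd.DataFrame(part_rows)

    run_rows = []
    for prow in participants.itertuples(index=False):
        for session in range(1, spec.sessions + 1):
            rng_s = _rng(spec.seed, 400, prow.p_idx, session)
            start = float(_sample_scan_hours(rng_s, spec, 1)[0])
            # day-to-day arousal/state noise, shared by the session's runs
            sess_eff = float(_rng(effects.seed, 450, prow.p_idx, session)
                             .normal(0.0, effects.session_amp_sd))
            for run in range(1, spec.runs_per_session + 1):
                hour = start + (run - 1) * spec.run_duration_h
                rng_r = _rng(effects.seed, 500, prow.p_idx, session, run)
                rv = (effects.rv_base
                      + effects.beta_tod_rv * (hour - 12.0)
                      + prow.rv_subject
                      + float(rng_r.normal(0.0, effects.rv_run_sd)))
                rv = float(np.clip(rv, 0.02, 0.9))
                run_noise = float(rng_r.normal(0.0, effects.amp_run_sd))
                amp = true_amplitude(effects, hour, run, rv,
                                     prow.family_effect,
                                     prow.subject_effect + sess_eff + run_noise)
                u = float(rng_r.uniform())
                if u < effects.flatline_fraction:
                    mode = "flatline_48"
                elif u < effects.flatline_fraction + effects.arrhythmia_fraction:
                    mode = "arrhythmia"
                else:
                    mode = "normal"
                run_rows.append({
                    "participant_id": prow.participant_id,
                    "family_id": prow.family_id, "p_idx": prow.p_idx,
                    "session": session, "run": run, "scan_hour": hour,
                    "true_amp": amp, "true_rv_sd": rv, "pulse_mode": mode,
                    "tr_s": spec.tr_seconds, "n_frames": spec.n_frames,
                })
    manifest = pd.DataFrame(run_rows)
    return Cohort(spec=spec, effects=effects, participants=participants,
                  manifest=manifest)


# ---------------------------------------------------------------------------
# run-level generators

def simulate_bold(
    ctx: RunContext,
    effects: EffectParams,
    return_noise: bool = False,
) -> ParcellatedBOLD | tuple[ParcellatedBOLD, np.ndarray]:
    """Generate one run's parcellated BOLD matrix.

    All regions carry the shared global process with unit loading; each
    network additionally carries a shared process sized so the expected
    within-network correlation matches ``network_block_corr`` (optionally
    modulated by hour via ``network_tod_slopes``).  With ``return_noise``
    the white-noise component (the run's unstructured-noise table, used
    for DVARS dips) is returned alongside.
    """
    spec = ctx.spec
    if spec.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = _rng(effects.seed, 600, ctx.p_idx, ctx.session, ctx.run)
    F, R = spec.n_frames, spec.n_regions
    labels, cortical = default_network_labels(R, spec.n_cortical)
    networks = list(dict.fromkeys(labels))  # unique, order preserved
    tau = 5.0  # smoothness of shared processes, seconds

    g = ctx.true_amp * _smooth_unit(rng, F, spec.tr_seconds, tau)[:, 0]
    U = _smooth_unit(rng, F, spec.tr_seconds, tau, size=len(networks))
    b = np.empty(len(networks))
    for k, name in enumerate(networks):
        c = effects.network_block_corr
        c += effects.network_tod_slopes.get(name, 0.0) * (ctx.scan_hour - 12.0)
        c = float(np.clip(c, 0.0, 0.95))
        b[k] = effects.noise_sd * np.sqrt(c / (1.0 - c))

    noise = rng.standard_normal((F, R)) * effects.noise_sd
    n_bursts = rng.poisson(effects.noise_burst_rate)
    if n_bursts > 0:
        burst_frames = rng.choice(F, size=min(n_bursts, F), replace=False)
        noise[burst_frames] *= effects.noise_burst_gain

    net_index = np.array([networks.index(l) for l in labels])
    data = 10_000.0 + g[:, None] + U[:, net_index] * b[net_index] + noise
    bold = ParcellatedBOLD(data=data, region_labels=[f"roi{i + 1:03d}" for i in range(R)],
                           network_labels=labels, cortical_mask=cortical,
                           tr_seconds=spec.tr_seconds)
    if return_noise:
        return bold, noise
    return bold


def simulate_respiration(ctx: RunContext, effects: EffectParams) -> np.ndarray:
    """Quasi-sinusoidal respiratory waveform whose windowed-SD level (after
    z-scoring) matches the run's latent RV SD target.

    The breathing envelope is ``1 + m * s(t)`` with ``s`` a smooth unit-SD
    process; since z-scoring removes overall scale, the modulation depth
    ``m = rv / sqrt(1 - rv^2)`` fixes the ratio of RV SD to RV mean and
    hence the RV SD in z-units.  Occasional sighs (large transient breaths)
    and slow breathing-rate jitter are added on top; both are disabled by
    setting their parameters to 0.  Sighing is itself a facet of dynamic
    breathing, so the sigh rate scales with the run's RV level
    (``resp_sigh_rate_per_min`` applies at the baseline ``rv_base``).
    """
    spec = ctx.spec
    rng = _rng(effects.seed, 700, ctx.p_idx, ctx.session, ctx.run)
    fs = spec.physio_hz
    n = int(round(spec.run_duration_s * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    def slow_process(tau_s: float) -> np.ndarray:
        # envelope/rate modulations live on >10 s timescales: generate on a
        # 4 Hz grid and interpolate, re-standardising on the fine grid
        dt_c = 0.25
        n_c = max(int(np.ceil(spec.run_duration_s / dt_c)) + 2, 8)
        coarse = _smooth_unit(rng, n_c, dt_c, tau_s)[:, 0]
        fine = np.interp(t, np.arange(n_c) * dt_c, coarse)
        fine = fine - fine.mean()
        sd = fine.std(ddof=1)
        return fine / sd if sd > 0 else fine

    r = float(np.clip(ctx.true_rv_sd, 0.0, 0.95))
    m = r / np.sqrt(1.0 - r**2)
    if m > 0:
        env = 1.0 + m * slow_process(15.0)
    else:
        env = np.ones(n)
    env = np.maximum(env, 0.05)

    if effects.resp_freq_jitter > 0:
        f_inst = effects.resp_freq_hz * (
            1.0 + effects.resp_freq_jitter * slow_process(20.0))
    else:
        f_inst = np.full(n, effects.resp_freq_hz)
    f_inst = np.maximum(f_inst, 0.02)
    phase = 2.0 * np.pi * np.cumsum(f_inst) * dt
    x = env * np.sin(phase + rng.uniform(0.0, 2.0 * np.pi))

    rel_rv = r / effects.rv_base if effects.rv_base > 0 else 1.0
    sigh_rate = effects.resp_sigh_rate_per_min * rel_rv
    n_sighs = rng.poisson(sigh_rate * spec.run_duration_s / 60.0)
    for _ in range(n_sighs):
        t0 = rng.uniform(0.0, spec.run_duration_s)
        x += 3.0 * np.exp(-0.5 * ((t - t0) / 1.5) ** 2)
    return x


def simulate_pulse(ctx: RunContext, effects: EffectParams,
                   mode: str | None = None) -> np.ndarray:
    """Pulse-like waveform with peaks at interbeat intervals.

    Normal mode draws IBIs from a positive AR(1) process (mean per
    participant, SD ``ibi_sd_s``, lag-1 coefficient ``ibi_ar``).  Artifact
    modes: ``"flatline_48"`` produces a metronomic 48.0 bpm train;
    ``"arrhythmia"`` alternates 0.6 s / 1.4 s intervals.
    """
    spec = ctx.spec
    rng = _rng(effects.seed, 800, ctx.p_idx, ctx.session, ctx.run)
    fs = spec.physio_hz
    duration = spec.run_duration_s
    n = int(round(duration * fs))
    mode = mode or ctx.pulse_mode

    beat_times = []
    t_beat = float(rng.uniform(0.0, 0.5))
    prev_dev = 0.0
    k = 0
    while t_beat < duration:
        beat_times.append(t_beat)
        if mode == "flatline_48":
            ibi = 60.0 / 48.0
        elif mode == "arrhythmia":
            ibi = (0.6 if k % 2 == 0 else 1.4) + float(rng.normal(0.0, 0.005))
        else:
            prev_dev = (effects.ibi_ar * prev_dev
                        + np.sqrt(max(1.0 - effects.ibi_ar**2, 0.0))
                        * float(rng.normal(0.0, effects.ibi_sd_s)))
            ibi = ctx.ibi_mean_s + prev_dev
        t_beat += max(ibi, 0.3)
        k += 1

    if effects.pulse_noise_sd > 0:
        x = rng.normal(0.0, effects.pulse_noise_sd, size=n)
    else:
        x = np.zeros(n)
    sigma_s = 0.05
    half = int(round(4 * sigma_s * fs))
    kt = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * (kt / sigma_s) ** 2)
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        x[lo:hi] += kernel[(lo - (c - half)):(hi - (c - half))]
    return x


def simulate_physio(ctx: RunContext, effects: EffectParams) -> PhysioTrace:
    """Bundle the respiration and pulse channels into a :class:`PhysioTrace`."""
    return PhysioTrace(
        sampling_hz=ctx.spec.physio_hz,
        respiration=simulate_respiration(ctx, effects),
        pulse=simulate_pulse(ctx, effects),
    )


def simulate_motion(ctx: RunContext, effects: EffectParams) -> np.ndarray:
    """Six-parameter motion trace: smooth low-amplitude drift plus
    Poisson-count single-frame spikes in random parameters."""
    spec = ctx.spec
    if spec.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = _rng(effects.seed, 900, ctx.p_idx, ctx.session, ctx.run)
    F = spec.n_frames
    params = np.zeros((F, 6))
    if effects.motion_drift_mm > 0:
        drift = _smooth_unit(rng, F, spec.tr_seconds, 30.0, size=6)
        drift *= effects.motion_drift_mm
        drift[:, 3:] /= 50.0  # rotations drift comparable in arc length
        params += drift
    n_spikes = rng.poisson(effects.motion_spike_rate)
    for _ in range(n_spikes):
        frame = int(rng.integers(1, F))
        col = int(rng.integers(0, 6))
        mag = float(rng.normal(effects.motion_spike_mm, 0.1 * effects.motion_spike_mm))
        mag = abs(mag) * (1 if rng.uniform() < 0.5 else -1)
        if col >= 3:
            mag /= 50.0
        params[frame, col] += mag
    return params


# ---------------------------------------------------------------------------
# calibration

def calibrate_tod_slope(
    spec: CohortSpec,
    effects: EffectParams,
    target_rho: float,
) -> float:
    """Direct time-of-day slope on GS amplitude that yields a population
    between-participant correlation ``target_rho`` at the session level.

    Uses the variance decomposition of the session-averaged amplitude:
    between-participant variance not attributable to time of day is
    ``subject_amp_sd^2 + family_re_sd^2 + session_amp_sd^2 +
    gamma^2 rv_subject_sd^2`` plus
    the run-level amplitude noise (``amp_run_sd`` and the RV run noise
    leaking through the coupling, both reduced by run averaging).  The
    total effective slope also includes the indirect path
    ``gamma_rv_gs * beta_tod_rv``, which is subtracted to return the
    direct slope.  The shared component is generated with exact sample SD,
    so SD-estimation error contributes nothing here; small network/noise
    inflation of the measured fluctuation is ignored.
    """
    if not (-1.0 < target_rho < 1.0):
        raise ValueError("target_rho must lie in (-1, 1)")
    sigma_h = scan_hour_sd(spec)
    n_runs = spec.runs_per_session
    meas_var = (effects.amp_run_sd**2
                + effects.gamma_rv_gs**2 * effects.rv_run_sd**2) / n_runs
    resid_var = (effects.subject_amp_sd**2 + effects.family_re_sd**2
                 + effects.session_amp_sd**2
                 + effects.gamma_rv_gs**2 * effects.rv_subject_sd**2
                 + meas_var)
    beta_eff = target_rho * np.sqrt(resid_var) / (
        sigma_h * np.sqrt(1.0 - target_rho**2))
    return float(beta_eff - effects.gamma_rv_gs * effects.beta_tod_rv)


def replace(obj, **changes):
    """`dataclasses.replace` re-exported for convenient spec/effects tweaking."""
    return dataclasses.replace(obj, **changes)
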