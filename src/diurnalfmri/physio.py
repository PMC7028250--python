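"""Respiratory-variation and heart-rate metrics from raw physiological logs.

Respiration: the raw waveform is z-scored, zero-phase low-pass filtered at
2 Hz, and summarised as respiratory variation (RV) — the sample SD of the
filtered waveform in 5.76-second sliding windows centred on each fMRI
frame (eight frames at TR = 0.72 s).  ``rv_summary`` reduces the RV series
to its per-run SD and mean.

Pulse: instantaneous heart rate is computed at each detected pulse peak
from the preceding interbeat interval (HR = 60/IBI); run-level summaries
are mean HR, HR SD, and HR RMSSD (root mean square of successive HR
differences).  ``physio_qc`` is an automated analogue of the study's
visual screening: it flags the 48.0-bpm flatline artefact, arrhythmic
runs via Poincare dispersion, excess ectopic beats, and respiratory
traces dominated by high-frequency artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PhysioTrace",
    "RVSeries",
    "PulsePeaks",
    "QCResult",
    "preprocess_respiration",
    "compute_rv",
    "rv_summary",
    "rv_window_extent_frames",
    "detect_pulse_peaks",
    "hr_summary",
    "physio_qc",
    "poincare_sd1",
    "robust_sd1_bound",
]

#: flag names used in PulsePeaks.qc_flags / QCResult.flags
FLATLINE_48 = "flatline_48"
ARRHYTHMIA_OUTLIER = "arrhythmia_outlier"
UNDETECTABLE_PEAKS = "undetectable_peaks"
RESP_HIGHFREQ = "resp_highfreq"


@dataclass
class PhysioTrace:
    """Respiration and pulse waveforms sampled at a fixed rate."""

    sampling_hz: float
    respiration: np.ndarray
    pulse: np.ndarray
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.respiration = np.asarray(self.respiration, dtype=float).ravel()
        self.pulse = np.asarray(self.pulse, dtype=float).ravel()
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.respiration.size != self.pulse.size:
            raise ValueError("respiration and pulse channels must have equal length")

    @property
    def duration_s(self) -> float:
        return self.respiration.size / self.sampling_hz


@dataclass
class RVSeries:
    """Windowed-SD respiratory variation, one value per fMRI frame."""

    values: np.ndarray
    window_seconds: float
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0):
            raise ValueError("RV values must be non-negative")


@dataclass
class PulsePeaks:
    """Detected pulse peaks, interbeat intervals and instantaneous HR."""

    peak_times: np.ndarray
    ibis: np.ndarray
    hr_at_peak: np.ndarray
    qc_flags: set = field(default_factory=set)

    @property
    def n_peaks(self) -> int:
        return self.peak_times.size


@dataclass
class QCResult:
    """Automated quality-control verdict for one run."""

    pulse_pass: bool
    resp_pass: bool
    flags: set
    details: dict


def preprocess_respiration(
    trace: PhysioTrace | np.ndarray,
    sampling_hz: float | None = None,
    cutoff_hz: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Z-score the respiration channel and low-pass filter it (zero phase).

    Returns the filtered waveform.  Raises on a zero-variance channel or on
    traces shorter than 10 s.
    """
    if isinstance(trace, PhysioTrace):
        x, fs = trace.respiration, trace.sampling_hz
    else:
        x = np.asarray(trace, dtype=float).ravel()
        if sampling_hz is None:
            raise ValueError("sampling_hz is required for a bare array")
        fs = float(sampling_hz)
    if x.size / fs < 10.0:
        raise ValueError("need at least 10 s of respiratory data")
    sd = np.std(x)
    if sd == 0:
        raise ValueError("respiration channel has zero variance")
    z = (x - x.mean()) / sd
    if cutoff_hz >= fs / 2:
        # already band-limited by the sampling rate; nothing to remove
        return z
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, z)


def rv_window_extent_frames(window_seconds: float = 5.76, tr_seconds: float = 0.72) -> float:
    """Extent of the RV window expressed in fMRI frames (window / TR)."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return window_seconds / tr_seconds


def compute_rv(
    waveform: np.ndarray,
    sampling_hz: float,
    n_frames: int,
    tr_seconds: float,
    window_seconds: float = 5.76,
) -> RVSeries:
    """Sliding-window SD of the respiratory waveform, one value per frame.

    Each window is centred on the acquisition midpoint of its frame,
    ``(i + 0.5) * TR``; windows are truncated at run boundaries so the
    series always has length ``n_frames``.  Sample SD (N-1) is used.
    """
    x = np.asarray(waveform, dtype=float).ravel()
    fs = float(sampling_hz)
    if window_seconds * fs < 2:
        raise ValueError("window must span at least 2 samples")
    run_duration = n_frames * tr_seconds
    if x.size / fs + 0.5 * window_seconds < run_duration - 1e-9:
        raise ValueError("waveform does not span the fMRI run")

    t = np.arange(x.size) / fs
    centers = (np.arange(n_frames) + 0.5) * tr_seconds
    lo = np.searchsorted(t, centers - window_seconds / 2.0, side="left")
    hi = np.searchsorted(t, centers + window_seconds / 2.0, side="right")

    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])
    n = (hi - lo).astype(float)
    if np.any(n < 2):
        raise ValueError("a window contains fewer than 2 samples")
    mean = (csum[hi] - csum[lo]) / n
    var = (csq[hi] - csq[lo]) / n - mean**2
    var = np.maximum(var, 0.0) * n / (n - 1.0)
    return RVSeries(values=np.sqrt(var), window_seconds=window_seconds,
                    tr_seconds=tr_seconds)


def rv_summary(rv: RVSeries) -> tuple[float, float]:
    """Return ``(rv_sd, rv_mean)`` over frames (sample SD, N-1)."""
    v = rv.values
    if v.size < 2:
        raise ValueError("need at least 2 frames of RV")
    return float(np.std(v, ddof=1)), float(v.mean())


def detect_pulse_peaks(
    trace: PhysioTrace | np.ndarray,
    sampling_hz: float | None = None,
    min_distance_s: float = 0.25,
    smooth_hz: float | None = 10.0,
) -> PulsePeaks:
    """Locate pulse-wave peaks and derive interbeat intervals.

    The waveform is first low-pass filtered at ``smooth_hz`` (pulse-ox
    waveforms carry no cardiac information above ~10 Hz, and denoising
    before peak picking stabilises the timing), then local maxima are found
    with a 0.25 s minimum inter-peak distance and a prominence threshold
    adapted to the waveform's amplitude range.  Peak times are refined to
    sub-sample precision by parabolic interpolation.  Fewer than 2
    detectable peaks yields an ``undetectable_peaks`` flag and empty
    interval arrays.
    """
    if isinstance(trace, PhysioTrace):
        x, fs = trace.pulse, trace.sampling_hz
    else:
        x = np.asarray(trace, dtype=float).ravel()
        if sampling_hz is None:
            raise ValueError("sampling_hz is required for a bare array")
        fs = float(sampling_hz)
    if x.size / fs < 10.0:
        raise ValueError("need at least 10 s of pulse data")
    if smooth_hz is not None and smooth_hz < fs / 2 and np.ptp(x) > 0:
        sos = sps.butter(2, smooth_hz, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)

    empty = PulsePeaks(np.array([]), np.array([]), np.array([]),
                       qc_flags={UNDETECTABLE_PEAKS})
    spread = np.percentile(x, 95) - np.percentile(x, 5)
    if spread <= 0:
        return empty
    idx, _ = sps.find_peaks(
        x, distance=max(1, int(round(min_distance_s * fs))),
        prominence=0.25 * spread,
    )
    if idx.size < 2:
        return empty

    times = idx.astype(float)
    interior = (idx > 0) & (idx < x.size - 1)
    i = idx[interior]
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    shift = np.zeros_like(i, dtype=float)
    ok = denom != 0
    shift[ok] = 0.5 * (x[i - 1] - x[i + 1])[ok] / denom[ok]
    times[interior] += np.clip(shift, -0.5, 0.5)
    times /= fs

    ibis = np.diff(times)
    if np.any(ibis <= 0):  # pragma: no cover - distance constraint prevents this
        return empty
    return PulsePeaks(peak_times=times, ibis=ibis, hr_at_peak=60.0 / ibis)


def hr_summary(peaks: PulsePeaks) -> tuple[float, float, float]:
    """Return ``(hr_mean, hr_sd, hr_rmssd)`` in bpm.

    Requires at least 3 peaks (2 instantaneous HR values).  RMSSD is the
    root mean square of successive differences of instantaneous HR.
    """
    hr = peaks.hr_at_peak
    if hr.size < 2:
        raise ValueError("need at least 3 peaks (2 HR values)")
    hr_mean = float(hr.mean())
    hr_sd = float(np.std(hr, ddof=1))
    diffs = np.diff(hr)
    hr_rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0
    return hr_mean, hr_sd, hr_rmssd


def poincare_sd1(ibis: np.ndarray) -> float:
    """Dispersion of successive IBI pairs perpendicular to the identity line."""
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size < 3:
        return 0.0
    return float(np.std(np.diff(ibis), ddof=1) / np.sqrt(2.0))


def robust_sd1_bound(sd1_values: np.ndarray, k: float = 6.0) -> float:
    """Cohort-level outlier bound: median + k robust SDs (MAD-based)."""
    v = np.asarray(sd1_values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return float(med + k * 1.4826 * mad)


def physio_qc(
    peaks: PulsePeaks | None = None,
    resp_filtered: np.ndarray | None = None,
    sampling_hz: float | None = None,
    *,
    flatline_hr: float = 48.0,
    flatline_hr_tol: float = 0.2,
    flatline_rmssd_tol: float = 0.5,
    sd1_bound: float = 0.1,
    ibi_range: tuple[float, float] = (0.3, 2.0),
    max_ectopic: int = 2,
    resp_hf_cutoff_hz: float = 1.0,
    resp_hf_max_fraction: float = 0.3,
) -> QCResult:
    """Automated screening of one run's pulse and respiration channels.

    Pulse fails on: undetectable peaks; a mean HR within ``flatline_hr_tol``
    of 48.0 bpm together with RMSSD below ``flatline_rmssd_tol`` (a known
    hardware artefact); Poincare SD1 above ``sd1_bound`` seconds; or more
    than ``max_ectopic`` interbeat intervals outside ``ibi_range`` (isolated
    out-of-range intervals are deleted before computing the summaries).
    Respiration fails when more than ``resp_hf_max_fraction`` of the
    post-filter spectral power lies above ``resp_hf_cutoff_hz``.

    These thresholds are configurable proxies for the study's visual QC,
    not a replication of it.
    """
    flags: set = set()
    details: dict = {}
    pulse_pass = True
    resp_pass = True

    if peaks is not None:
        if UNDETECTABLE_PEAKS in peaks.qc_flags or peaks.n_peaks < 3:
            flags.add(UNDETECTABLE_PEAKS)
            pulse_pass = False
        else:
            lo, hi = ibi_range
            ibis = peaks.ibis
            out_of_range = (ibis < lo) | (ibis > hi)
            n_ectopic = int(out_of_range.sum())
            details["n_ectopic"] = n_ectopic
            clean = ibis[~out_of_range]
            if n_ectopic > max_ectopic or clean.size < 2:
                flags.add(ARRHYTHMIA_OUTLIER)
                pulse_pass = False
            else:
                hr = 60.0 / clean
                hr_mean = float(hr.mean())
                rmssd = float(np.sqrt(np.mean(np.diff(hr) ** 2))) if hr.size > 1 else 0.0
                sd1 = poincare_sd1(clean)
                details.update(hr_mean=hr_mean, hr_rmssd=rmssd, poincare_sd1=sd1)
                if abs(hr_mean - flatline_hr) < flatline_hr_tol and rmssd < flatline_rmssd_tol:
                    flags.add(FLATLINE_48)
                    pulse_pass = False
                if sd1 > sd1_bound:
                    flags.add(ARRHYTHMIA_OUTLIER)
                    pulse_pass = False

    if resp_filtered is not None:
        if sampling_hz is None:
            raise ValueError("sampling_hz is required for respiratory QC")
        x = np.asarray(resp_filtered, dtype=float).ravel()
        nperseg = min(x.size, int(round(30.0 * sampling_hz)))
        freqs, psd = sps.welch(x, fs=sampling_hz, nperseg=max(nperseg, 16))
        total = float(np.trapezoid(psd, freqs))
        if total > 0:
            hf = float(np.trapezoid(psd[freqs > resp_hf_cutoff_hz],
                                    freqs[freqs > resp_hf_cutoff_hz]))
            frac = hf / total
        else:
            frac = 0.0
        details["resp_hf_fraction"] = frac
        if frac > resp_hf_max_fraction:
            flags.add(RESP_HIGHFREQ)
            resp_pass = False

    return QCResult(pulse_pass=pulse_pass, resp_pass=resp_pass,
                    flags=flags, details=details)
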