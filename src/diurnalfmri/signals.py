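"""Global-signal and regional BOLD fluctuation metrics.

The global signal (GS) is the unweighted mean BOLD time series across
cortical parcels (optionally across all parcels).  Its temporal standard
deviation — the *GS fluctuation* — is the central quantity of the
time-of-day analyses: on grand-mean-10,000 scaled data it converts to
percent signal change by dividing by 10,000 and multiplying by 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ParcellatedBOLD",
    "GSSeries",
    "compute_gs",
    "gs_fluctuation",
    "to_percent_signal_change",
    "regional_fluctuation",
    "global_signal_regression",
    "session_average",
]

GSSource = Literal["cortical", "whole_brain"]


@dataclass
class ParcellatedBOLD:
    """Parcel-averaged BOLD data for one run.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, n_regions)`` in BOLD units on the
        grand-mean-10,000 scale.
    region_labels
        One identifier per region.
    network_labels
        Large-scale network assignment per region (17 cortical networks
        plus ``"Subcortex"`` by default).
    cortical_mask
        Boolean flag per region; True for cortical parcels.
    tr_seconds
        Repetition time of the acquisition.
    """

    data: np.ndarray
    region_labels: Sequence[str]
    network_labels: Sequence[str]
    cortical_mask: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.cortical_mask = np.asarray(self.cortical_mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be a frames x regions matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        n_regions = self.data.shape[1]
        if not (len(self.region_labels) == len(self.network_labels)
                == self.cortical_mask.size == n_regions):
            raise ValueError("label/mask lengths must match number of regions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.cortical_mask.any():
            raise ValueError("cortical_mask must select at least one region")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class GSSeries:
    """Global-signal time series and the mask it was averaged over."""

    values: np.ndarray
    source: GSSource = "cortical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def compute_gs(bold: ParcellatedBOLD, source: GSSource = "cortical") -> GSSeries:
    """Average the regional time series into the global signal.

    ``source="cortical"`` (default) averages cortical parcels only;
    ``source="whole_brain"`` averages every region.
    """
    if source == "cortical":
        mask = bold.cortical_mask
    elif source == "whole_brain":
        mask = np.ones(bold.n_regions, dtype=bool)
    else:  # pragma: no cover - guarded by Literal in typed callers
        raise ValueError(f"unknown GS source {source!r}")
    if not mask.any():
        raise ValueError("empty region mask")
    return GSSeries(values=bold.data[:, mask].mean(axis=1), source=source)


def gs_fluctuation(gs: GSSeries | np.ndarray) -> float:
    """Temporal standard deviation (sample SD, N-1) of the global signal."""
    values = gs.values if isinstance(gs, GSSeries) else np.asarray(gs, float)
    if values.size < 2:
        raise ValueError("need at least 2 frames to compute a fluctuation")
    return float(np.std(values, ddof=1))


def to_percent_signal_change(fluctuation: float) -> float:
    """Convert a BOLD-unit fluctuation on the grand-mean-10,000 scale to %."""
    return fluctuation / 10_000.0 * 100.0


def regional_fluctuation(bold: ParcellatedBOLD) -> np.ndarray:
    """Sample SD of each region's parcel-averaged series (length n_regions)."""
    if bold.n_frames < 2:
        raise ValueError("need at least 2 frames")
    return np.std(bold.data, axis=0, ddof=1)


def global_signal_regression(bold: ParcellatedBOLD) -> ParcellatedBOLD:
    """Regress the cortical global signal out of every region.

    Each regional series is replaced by the residuals of a least-squares
    fit on an intercept plus the GS, so residuals are mean-zero and exactly
    uncorrelated with the GS.  The operation is idempotent.
    """
    gs = compute_gs(bold, source="cortical").values
    gs_sd = np.std(gs)
    if gs_sd == 0:
        raise ValueError("global signal has zero variance; cannot regress")
    if gs_sd < 1e-10 * max(np.abs(bold.data).max(), 1.0):
        # GS is numerical noise (data already GS-regressed): only demean,
        # which keeps the operation exactly idempotent
        design = np.ones((bold.n_frames, 1))
    else:
        design = np.column_stack([np.ones_like(gs), gs])
    beta, *_ = np.linalg.lstsq(design, bold.data, rcond=None)
    residuals = bold.data - design @ beta
    return ParcellatedBOLD(
        data=residuals,
        region_labels=list(bold.region_labels),
        network_labels=list(bold.network_labels),
        cortical_mask=bold.cortical_mask.copy(),
        tr_seconds=bold.tr_seconds,
    )


def session_average(values: Iterable[float]) -> float:
    """Arithmetic mean of a metric over the runs available in a session."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("session_average requires at least one run value")
    return float(arr.mean())
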