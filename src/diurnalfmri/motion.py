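"""Head-motion metrics: FD, AD, DVARS, outlier censoring, DVARS dips.

Conventions: motion parameter tables hold three translations (mm) followed
by three rotations (radians); rotations are converted to millimetres as
arc length on a 50 mm sphere.  The first frame of any differentiated
metric (FD, DVARS) is 0 — it has no predecessor.  DVARS here is computed
over parcels rather than voxels, so the conventional threshold of 75 is
only meaningful on grand-mean-10,000 scaled data and is config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .signals import ParcellatedBOLD

__all__ = [
    "FrameMask",
    "compute_fd",
    "compute_ad",
    "compute_dvars",
    "outlier_frames",
    "dvars_dips",
    "session_exclusion",
]

ROTATION_RADIUS_MM = 50.0

FDVariant = Literal["sum_abs", "rms"]


@dataclass
class FrameMask:
    """Per-frame censoring mask with the rule that produced each entry.

    ``provenance`` holds ``"fd"``, ``"dvars"``, ``"fd+dvars"``,
    ``"padding"``, ``"short_segment"`` or ``""`` per frame.
    """

    outlier: np.ndarray
    provenance: np.ndarray

    @property
    def outlier_pct(self) -> float:
        return float(100.0 * self.outlier.mean())


def _as_params(motion: np.ndarray) -> np.ndarray:
    params = np.asarray(motion, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be a frames x 6 matrix")
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters contain non-finite values")
    return params


def _to_mm(params: np.ndarray, radius_mm: float) -> np.ndarray:
    out = params.copy()
    out[:, 3:] *= radius_mm
    return out


def compute_fd(
    motion: np.ndarray,
    radius_mm: float = ROTATION_RADIUS_MM,
    variant: FDVariant = "sum_abs",
) -> np.ndarray:
    """Framewise displacement in mm from a frames x 6 parameter table.

    ``variant="sum_abs"`` (default) is the Power-style sum of absolute
    backward differences after converting rotations to arc length;
    ``variant="rms"`` takes the per-frame root mean square of the six
    converted differences instead.  FD of the first frame is 0.
    """
    params = _to_mm(_as_params(motion), radius_mm)
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(params, axis=0)
    if variant == "sum_abs":
        fd = np.abs(d).sum(axis=1)
    elif variant == "rms":
        fd = np.sqrt((d**2).mean(axis=1))
    else:
        raise ValueError(f"unknown FD variant {variant!r}")
    return np.concatenate([[0.0], fd])


def compute_ad(
    motion: np.ndarray,
    radius_mm: float = ROTATION_RADIUS_MM,
    reference: Literal["target", "first_frame"] = "target",
    variant: FDVariant = "sum_abs",
) -> np.ndarray:
    """Absolute displacement in mm: the FD conversion applied to positions.

    With ``reference="target"`` (default) the parameters are used as given,
    i.e. relative to the realignment target at the coordinate origin; with
    ``reference="first_frame"`` the first frame is subtracted first.
    """
    params = _to_mm(_as_params(motion), radius_mm)
    if reference == "first_frame":
        params = params - params[0]
    elif reference != "target":
        raise ValueError(f"unknown AD reference {reference!r}")
    if variant == "sum_abs":
        return np.abs(params).sum(axis=1)
    if variant == "rms":
        return np.sqrt((params**2).mean(axis=1))
    raise ValueError(f"unknown FD variant {variant!r}")


def compute_dvars(bold: ParcellatedBOLD | np.ndarray) -> np.ndarray:
    """Root mean square over regions of the frame-differentiated signal.

    ``dvars[t] = sqrt(mean_r (x[t, r] - x[t-1, r])^2)``, with ``dvars[0] = 0``.
    """
    data = bold.data if isinstance(bold, ParcellatedBOLD) else np.asarray(bold, float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a frames x regions matrix with >= 2 frames")
    d = np.diff(data, axis=0)
    return np.concatenate([[0.0], np.sqrt((d**2).mean(axis=1))])


def outlier_frames(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_thresh: float = 0.2,
    dvars_thresh: float = 75.0,
    pad_before: int = 1,
    pad_after: int = 2,
    min_segment: int = 5,
) -> FrameMask:
    """Three-stage outlier-frame censoring mask.

    1. flag frames where FD or DVARS exceed their thresholds;
    2. also flag ``pad_before`` frames before and ``pad_after`` frames
       after each hit (clipped at run boundaries);
    3. convert every maximal run of surviving frames shorter than
       ``min_segment`` to outliers.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have equal length")
    n = fd.size
    fd_hit = fd > fd_thresh
    dv_hit = dvars > dvars_thresh
    hits = fd_hit | dv_hit

    provenance = np.full(n, "", dtype=object)
    provenance[fd_hit & ~dv_hit] = "fd"
    provenance[dv_hit & ~fd_hit] = "dvars"
    provenance[fd_hit & dv_hit] = "fd+dvars"

    mask = hits.copy()
    for i in np.flatnonzero(hits):
        lo = max(0, i - pad_before)
        hi = min(n, i + pad_after + 1)
        for j in range(lo, hi):
            if not mask[j]:
                mask[j] = True
                provenance[j] = "padding"

    # stage 3: censor short surviving segments
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        if j - i < min_segment:
            mask[i:j] = True
            provenance[i:j] = "short_segment"
        i = j

    return FrameMask(outlier=mask, provenance=np.asarray(provenance, dtype=object))


def dvars_dips(dvars: np.ndarray, deviation: float = 75.0) -> float:
    """Percentage of frames whose DVARS deviates >= ``deviation`` from the
    run's median DVARS (two-sided: dips and peaks).

    Intended to be computed on the DVARS of an unstructured-noise
    representation of the run, not of the full denoised signal.
    """
    dvars = np.asarray(dvars, dtype=float)
    if dvars.size == 0:
        raise ValueError("empty DVARS series")
    med = np.median(dvars)
    return float(100.0 * np.mean(np.abs(dvars - med) >= deviation))


def session_exclusion(outlier_pcts: Iterable[float], max_pct: float = 50.0) -> bool:
    """True (drop the session) if any run's outlier percentage exceeds
    ``max_pct`` (strict inequality: exactly 50% is kept)."""
    pcts = list(outlier_pcts)
    if not pcts:
        raise ValueError("no run masks supplied")
    return any(p > max_pct for p in pcts)
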