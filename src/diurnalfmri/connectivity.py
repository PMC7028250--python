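"""Resting-state functional connectivity matrices and network summaries.

RSFC for a run is the Pearson correlation matrix of the regional time
series; session-level matrices are elementwise means of the run matrices
(averaged on r).  Edge values can be correlated with a participant-level
covariate across the cohort, averaged within network blocks, and
summarised as the median absolute Fisher z over the lower triangle.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .signals import ParcellatedBOLD

__all__ = [
    "rsfc_matrix",
    "session_rsfc",
    "edgewise_covariate_corr",
    "network_average",
    "fisher_z",
    "median_abs_z",
]


def rsfc_matrix(bold: ParcellatedBOLD) -> np.ndarray:
    """Pairwise Pearson correlations of the regional series (diag = 1)."""
    if bold.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    sds = bold.data.std(axis=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        names = [bold.region_labels[i] for i in dead[:5]]
        raise ValueError(f"zero-variance region(s): {names}")
    corr = np.corrcoef(bold.data, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def session_rsfc(run_matrices: Sequence[np.ndarray],
                 average: str = "r") -> np.ndarray:
    """Elementwise mean of run-level RSFC matrices.

    Default averages on r; ``average="z"`` averages Fisher-z transforms
    and back-transforms (diagonal restored to 1).
    """
    mats = [np.asarray(m, dtype=float) for m in run_matrices]
    if not mats:
        raise ValueError("need at least one run matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("run matrices must share a shape")
    if average == "r":
        return np.mean(mats, axis=0)
    if average == "z":
        stacked = np.stack(mats)
        off = ~np.eye(shape[0], dtype=bool)
        out = np.ones(shape)
        out[off] = np.tanh(np.mean(np.arctanh(
            np.clip(stacked[:, off], -1 + 1e-15, 1 - 1e-15)), axis=0))
        return out
    raise ValueError(f"unknown average {average!r}")


def edgewise_covariate_corr(
    rsfc_stack: np.ndarray,
    covariate: np.ndarray,
) -> np.ndarray:
    """Correlate each edge with a participant-level covariate.

    Parameters
    ----------
    rsfc_stack
        Array ``(n_participants, n_regions, n_regions)`` of RSFC matrices.
    covariate
        One value per participant (e.g. scan hour); must be nonconstant.

    Returns
    -------
    Symmetric ``(n_regions, n_regions)`` matrix of Pearson r across
    participants (diagonal 0).
    """
    stack = np.asarray(rsfc_stack, dtype=float)
    cov = np.asarray(covariate, dtype=float).ravel()
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("rsfc_stack must be (participants, regions, regions)")
    n = stack.shape[0]
    if cov.size != n:
        raise ValueError("covariate length must match the stack")
    if n < 4:
        raise ValueError("need at least 4 participants")
    if np.std(cov) == 0:
        raise ValueError("covariate is constant")

    R = stack.shape[1]
    iu = np.triu_indices(R, k=1)
    edges = stack[:, iu[0], iu[1]]                     # n x E
    ez = edges - edges.mean(axis=0)
    esd = ez.std(axis=0)
    esd[esd == 0] = np.inf                             # constant edge -> r = 0
    cz = (cov - cov.mean()) / cov.std()
    r = (ez / esd).T @ cz / n

    out = np.zeros((R, R))
    out[iu] = r
    out += out.T
    return out


def network_average(
    edge_matrix: np.ndarray,
    network_labels: Sequence[str],
) -> pd.DataFrame:
    """Average edge values within network-pair blocks.

    Block (i, j) is the mean over all distinct region pairs with network
    labels {i, j}; diagonal entries of the region matrix (self pairs) are
    excluded so within-network blocks are not biased by the unit diagonal.
    """
    M = np.asarray(edge_matrix, dtype=float)
    labels = np.asarray(network_labels)
    if M.shape[0] != M.shape[1] or labels.size != M.shape[0]:
        raise ValueError("labels must cover all regions of a square matrix")
    nets = list(dict.fromkeys(labels))
    K = len(nets)
    out = np.full((K, K), np.nan)
    for a in range(K):
        ia = np.flatnonzero(labels == nets[a])
        for b_ in range(a, K):
            ib = np.flatnonzero(labels == nets[b_])
            block = M[np.ix_(ia, ib)]
            if a == b_:
                if ia.size < 2:
                    continue
                tri = np.triu_indices(ia.size, k=1)
                vals = block[tri]
            else:
                vals = block.ravel()
            out[a, b_] = out[b_, a] = float(np.mean(vals))
    return pd.DataFrame(out, index=nets, columns=nets)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z transform, ``z = atanh(r)``; requires |r| < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def median_abs_z(edge_matrix: np.ndarray) -> float:
    """Median absolute Fisher z over the strict lower triangle."""
    M = np.asarray(edge_matrix, dtype=float)
    il = np.tril_indices(M.shape[0], k=-1)
    return float(np.median(np.abs(fisher_z(M[il]))))
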