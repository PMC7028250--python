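"""Per-run summary table of nuisance metrics and correlation grids.

Thirteen run-level nuisance metrics are tracked alongside GS fluctuation
and scan time: outlier frames %, DVARS dips %, FD SD/mean, AD SD/mean,
DVARS SD/mean, RV SD/mean, HR RMSSD/SD/mean.  Physiological metrics are
only retained for sessions in which *both* runs passed that domain's
quality control; motion-excluded sessions are flagged.  The correlation
grid mirrors the study design: each metric is correlated with GS
fluctuation (or with time of day) across participants separately per run,
within the complete-case subgroup for its domain, with family-permutation
p-values and FDR stars at q < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .inference import between_participant_corr, fdr_correct

__all__ = [
    "NUISANCE_METRICS",
    "CARDIAC_METRICS",
    "RESPIRATORY_METRICS",
    "build_run_summaries",
    "metric_correlation_grid",
    "gs_tod_by_subgroup",
]

NUISANCE_METRICS = [
    "outlier_pct", "dvars_dips_pct", "fd_sd", "fd_mean", "ad_sd", "ad_mean",
    "dvars_sd", "dvars_mean", "rv_sd", "rv_mean", "hr_rmssd", "hr_sd", "hr_mean",
]
RESPIRATORY_METRICS = ["rv_sd", "rv_mean"]
CARDIAC_METRICS = ["hr_rmssd", "hr_sd", "hr_mean"]

_KEY = ["participant_id", "session", "run"]


def build_run_summaries(rows: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-run summary table with session-level QC masking.

    ``rows`` must contain one row per participant-run with the key columns
    ``participant_id, family_id, session, run, scan_hour``, the metric
    columns (any of :data:`NUISANCE_METRICS` plus ``gs_fluct``), and the
    QC flags ``resp_pass`` / ``pulse_pass`` (booleans).  Respiratory and
    cardiac metrics are set to NaN for *both* runs of any session in which
    either run failed that domain's QC.  Sessions with a run exceeding 50%
    outlier frames are flagged ``excluded``.
    """
    df = rows.copy()
    if df.duplicated(subset=_KEY).any():
        raise ValueError("duplicate participant-run rows")

    grp = df.groupby(["participant_id", "session"])
    if "resp_pass" in df:
        ok = grp["resp_pass"].transform("all")
        df.loc[~ok, RESPIRATORY_METRICS] = np.nan
        df["resp_domain_ok"] = ok
    if "pulse_pass" in df:
        ok = grp["pulse_pass"].transform("all")
        df.loc[~ok, [m for m in CARDIAC_METRICS if m in df]] = np.nan
        df["cardiac_domain_ok"] = ok
    if "outlier_pct" in df:
        df["excluded"] = grp["outlier_pct"].transform(lambda s: (s > 50.0).any())
    else:
        df["excluded"] = False
    return df


def _stars(p_col: np.ndarray, qs: Sequence[float]) -> list[str]:
    """FDR the whole grid at each threshold; one star per passed threshold."""
    marks = np.zeros(p_col.size, dtype=int)
    for q in sorted(qs, reverse=True):
        reject, _ = fdr_correct(p_col, q=q)
        marks += reject.astype(int)
    return ["*" * m for m in marks]


def metric_correlation_grid(
    summaries: pd.DataFrame,
    target: Literal["gs_fluct", "scan_hour"] = "gs_fluct",
    metrics: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    qs: Sequence[float] = (0.05, 0.01, 0.001),
    min_n: int = 4,
) -> pd.DataFrame:
    """Between-participant correlation of each metric with ``target``,
    separately per (session, run), with FDR stars across the whole grid.

    Complete-case analysis per metric: rows with a NaN metric (QC-masked)
    or flagged ``excluded`` are dropped for that metric only, so each
    domain is evaluated in its own QC subgroup.  Metrics whose subgroup
    has fewer than ``min_n`` participants or zero variance are skipped
    with a warning.
    """
    metrics = list(metrics) if metrics is not None else list(NUISANCE_METRICS)
    out_rows = []
    base = summaries[~summaries["excluded"].astype(bool)]
    for (session, run), chunk in base.groupby(["session", "run"]):
        for metric in metrics:
            if metric not in chunk:
                continue
            sub = chunk.dropna(subset=[metric, target])
            if len(sub) < min_n:
                warnings.warn(
                    f"{metric} session {session} run {run}: n={len(sub)} < {min_n}, skipped")
                continue
            m = sub[metric].to_numpy(float)
            t = sub[target].to_numpy(float)
            if np.std(m) == 0 or np.std(t) == 0:
                warnings.warn(f"{metric} session {session} run {run}: constant, skipped")
                continue
            cell_seed = seed + 1009 * metrics.index(metric) + 31 * int(session) + int(run)
            res = between_participant_corr(
                m, t, sub["family_id"].to_numpy(), n_perm=n_perm, seed=cell_seed)
            out_rows.append({"metric": metric, "session": session, "run": run,
                             "n": res.n, "r": res.r, "p": res.p})
    grid = pd.DataFrame(out_rows)
    if len(grid):
        grid["stars"] = _stars(grid["p"].to_numpy(), qs)
    return grid


def gs_tod_by_subgroup(
    summaries: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """GS fluctuation vs time of day, recomputed within each QC subgroup.

    Session-level (run-averaged) between-participant correlations for the
    motion subgroup (all non-excluded sessions), and where the QC columns
    exist, the respiratory and cardiac complete-case subgroups.
    """
    rows = []
    base = summaries[~summaries["excluded"].astype(bool)]
    domains = {"motion": None, "respiratory": "resp_domain_ok",
               "cardiac": "cardiac_domain_ok"}
    for session, chunk in base.groupby("session"):
        sess = (chunk.groupby(["participant_id", "family_id"])
                [["gs_fluct", "scan_hour"]].mean().reset_index())
        for name, flag in domains.items():
            sub = sess
            if flag is not None:
                if flag not in chunk:
                    continue
                keep = chunk.groupby("participant_id")[flag].all()
                sub = sess[sess["participant_id"].map(keep)]
            if len(sub) < 4:
                continue
            res = between_participant_corr(
                sub["gs_fluct"].to_numpy(float), sub["scan_hour"].to_numpy(float),
                sub["family_id"].to_numpy(), n_perm=n_perm, seed=seed)
            rows.append({"session": session, "subgroup": name, "n": res.n,
                         "r": res.r, "p": res.p})
    return pd.DataFrame(rows)
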