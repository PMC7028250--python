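"""End-to-end orchestration: simulate -> per-run metrics -> analyses.

``run_pipeline`` sequences the full analysis: motion-based session
exclusion, the 13 per-run nuisance metrics, session aggregation,
between-/within-participant time-of-day correlations, the metric
correlation grids, regional fluctuation maps with FDR, edgewise RSFC
correlations with network averaging and the network-based statistic,
optional GSR variants of the regional and RSFC analyses, and an
OLS/robust/quantile fit comparison.  Every output is stamped with the
config hash and seed; results are returned in memory and optionally
written as CSV tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cohort import Cohort, CohortSpec, EffectParams, simulate_bold, simulate_cohort, simulate_motion, simulate_physio
from .connectivity import edgewise_covariate_corr, median_abs_z, network_average, rsfc_matrix
from .inference import (between_participant_corr, build_permutation_scheme,
                        fdr_correct, fit_lines, network_based_statistic,
                        paired_run_test, regress_covariate,
                        within_participant_corr)
from .motion import compute_ad, compute_dvars, compute_fd, dvars_dips, outlier_frames
from .physio import compute_rv, detect_pulse_peaks, hr_summary, physio_qc, preprocess_respiration, rv_summary
from .signals import compute_gs, global_signal_regression, gs_fluctuation, regional_fluctuation, to_percent_signal_change
from .summaries import build_run_summaries, gs_tod_by_subgroup, metric_correlation_grid

__all__ = ["AnalysisConfig", "run_pipeline", "windowed_means"]


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run.

    Either ``spec`` (simulate in memory) or ``cohort_dir`` (read a
    materialised cohort) must be provided.
    """

    spec: CohortSpec | None = None
    effects: EffectParams | None = None
    cohort_dir: str | None = None
    gs_source: str = "cortical"
    fd_thresh: float = 0.2
    dvars_thresh: float = 75.0
    dips_deviation: float = 75.0
    n_permutations: int = 999
    q: float = 0.05
    nbs_edge_p: float = 0.001
    gsr: bool = False
    with_physio: bool = True
    with_motion: bool = True
    regression_methods: tuple = ("ols", "robust_huber", "quantile_median")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fd_thresh", "dvars_thresh", "dips_deviation", "q", "nbs_edge_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        spec = CohortSpec(**raw.pop("spec")) if "spec" in raw else None
        effects = EffectParams(**raw.pop("effects")) if "effects" in raw else None
        return cls(spec=spec, effects=effects, **raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def windowed_means(values: np.ndarray, hours: np.ndarray,
                   width: float = 1.0, anchor: float = 0.0) -> pd.DataFrame:
    """Mean and standard error of ``values`` in fixed clock-time windows.

    Windows of ``width`` hours are anchored on the hour grid (e.g. hourly
    windows [8,9), [9,10), ... for between-participant plots; 3-hourly for
    within-participant deltas)."""
    values = np.asarray(values, float)
    hours = np.asarray(hours, float)
    idx = np.floor((hours - anchor) / width).astype(int)
    rows = []
    for k in np.unique(idx):
        sel = idx == k
        v = values[sel]
        rows.append({
            "window_start": anchor + k * width,
            "window_center": anchor + (k + 0.5) * width,
            "n": int(sel.sum()),
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def _vector_corr_perm(values: np.ndarray, covariate: np.ndarray,
                      families, n_perm: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of ``values`` with ``covariate`` plus
    family-permutation two-sided p-values (shared permutations)."""
    V = np.asarray(values, float)
    c = np.asarray(covariate, float)
    n = c.size
    Vz = V - V.mean(axis=0)
    sd = Vz.std(axis=0)
    sd[sd == 0] = np.inf
    Vz /= sd
    cz = (c - c.mean()) / c.std()
    r = Vz.T @ cz / n
    scheme = build_permutation_scheme(families, seed=seed)
    P = scheme.draw_matrix(n_perm)
    nulls = Vz.T @ cz[P].T / n          # R x n_perm
    count = (np.abs(nulls) >= np.abs(r)[:, None]).sum(axis=1)
    p = (1.0 + count) / (1.0 + n_perm)
    return r, p


def _session_table(run_metrics: pd.DataFrame, cols) -> pd.DataFrame:
    """Session-level (run-averaged) values per participant."""
    return (run_metrics.groupby(["participant_id", "family_id", "session"])
            [list(cols)].mean().reset_index())


def run_pipeline(config: AnalysisConfig, out_dir: str | Path | None = None,
                 overwrite: bool = False) -> dict:
    """Execute the full analysis; see module docstring for the stages.

    Returns a result bundle (dict of DataFrames plus ``info`` and ``log``);
    when ``out_dir`` is given the tables are also written as CSV, refusing
    to overwrite an existing non-empty directory unless ``overwrite``.
    """
    log: list[str] = []
    nperm = config.n_permutations
    seed = config.seed

    if config.cohort_dir is None:
        if config.spec is None:
            raise ValueError("config needs either a spec or a cohort_dir")
        cohort = simulate_cohort(config.spec, config.effects)
        runs = _iter_simulated(cohort, config)
        manifest = cohort.manifest
    else:
        manifest, runs = _iter_directory(config)
    log.append(f"cohort: {manifest['participant_id'].nunique()} participants, "
               f"{len(manifest)} runs")

    # ------------------------------------------------------------------ per-run
    rows = []
    regional, regional_gsr = {}, {}
    rsfc_acc, rsfc_gsr_acc = {}, {}
    for meta, bold, noise, physio, motion in runs:
        row = dict(meta)
        gs = compute_gs(bold, source=config.gs_source)
        row["gs_fluct"] = gs_fluctuation(gs)
        row["gs_fluct_pct"] = to_percent_signal_change(row["gs_fluct"])

        dvars = compute_dvars(bold)
        row["dvars_mean"] = float(dvars[1:].mean())
        row["dvars_sd"] = float(np.std(dvars[1:], ddof=1))
        noise_dvars = compute_dvars(noise) if noise is not None else dvars
        row["dvars_dips_pct"] = dvars_dips(noise_dvars, deviation=config.dips_deviation)

        if motion is not None:
            fd = compute_fd(motion)
            ad = compute_ad(motion)
            mask = outlier_frames(fd, dvars, fd_thresh=config.fd_thresh,
                                  dvars_thresh=config.dvars_thresh)
            row.update(fd_mean=float(fd[1:].mean()), fd_sd=float(np.std(fd[1:], ddof=1)),
                       ad_mean=float(ad.mean()), ad_sd=float(np.std(ad, ddof=1)),
                       outlier_pct=mask.outlier_pct)
        if physio is not None:
            try:
                resp = preprocess_respiration(physio)
                rv = compute_rv(resp, physio.sampling_hz, bold.n_frames,
                                bold.tr_seconds)
                row["rv_sd"], row["rv_mean"] = rv_summary(rv)
            except ValueError:
                resp = None
            peaks = detect_pulse_peaks(physio)
            qc = physio_qc(peaks, resp_filtered=resp,
                           sampling_hz=physio.sampling_hz)
            row["resp_pass"] = bool(qc.resp_pass and resp is not None)
            row["pulse_pass"] = bool(qc.pulse_pass)
            if qc.pulse_pass and peaks.n_peaks >= 3:
                row["hr_mean"], row["hr_sd"], row["hr_rmssd"] = hr_summary(peaks)
            else:
                row["hr_mean"] = row["hr_sd"] = row["hr_rmssd"] = np.nan

        key = (meta["participant_id"], meta["session"])
        regional.setdefault(key, []).append(regional_fluctuation(bold))
        rsfc_acc.setdefault(key, []).append(rsfc_matrix(bold))
        if config.gsr:
            bold_g = global_signal_regression(bold)
            regional_gsr.setdefault(key, []).append(regional_fluctuation(bold_g))
            rsfc_gsr_acc.setdefault(key, []).append(rsfc_matrix(bold_g))
        net_labels = list(bold.network_labels)
        rows.append(row)

    run_metrics = pd.DataFrame(rows)
    summaries = build_run_summaries(run_metrics)
    n_excl = int(summaries.loc[summaries["excluded"],
                               ["participant_id", "session"]]
                 .drop_duplicates().shape[0])
    log.append(f"motion exclusion: {n_excl} sessions dropped (>50% outliers)")

    keep = ~summaries["excluded"].astype(bool)
    kept = summaries[keep]

    # ------------------------------------------------------ ToD correlations
    tod_rows, fit_rows = [], []
    sess = _session_table(kept, ["gs_fluct", "gs_fluct_pct", "scan_hour"])
    for session, chunk in sess.groupby("session"):
        if len(chunk) < 4:
            log.append(f"session {session}: n={len(chunk)} < 4, "
                       "between-participant test skipped")
            continue
        res = between_participant_corr(chunk["gs_fluct"].to_numpy(),
                                       chunk["scan_hour"].to_numpy(),
                                       chunk["family_id"].to_numpy(),
                                       n_perm=nperm, seed=seed)
        tod_rows.append({"measure": "gs_fluct", "level": "between",
                         "session": session, "n": res.n, "r": res.r, "p": res.p})
        for method in config.regression_methods:
            slope, intercept = fit_lines(chunk["gs_fluct_pct"].to_numpy(),
                                         chunk["scan_hour"].to_numpy(), method)
            fit_rows.append({"session": session, "method": method,
                             "slope_pct_per_h": slope, "intercept_pct": intercept})

    both = sess.pivot_table(index=["participant_id", "family_id"],
                            columns="session",
                            values=["gs_fluct", "scan_hour"]).dropna()
    if len(both) >= 4 and sess["session"].nunique() >= 2:
        s1, s2 = sorted(sess["session"].unique())[:2]
        d_gs = (both[("gs_fluct", s2)] - both[("gs_fluct", s1)]).to_numpy()
        d_h = (both[("scan_hour", s2)] - both[("scan_hour", s1)]).to_numpy()
        fams = both.index.get_level_values("family_id").to_numpy()
        res = within_participant_corr(d_gs, d_h, fams, n_perm=nperm, seed=seed)
        tod_rows.append({"measure": "gs_fluct", "level": "within", "session": 0,
                         "n": res.n, "r": res.r, "p": res.p})
        windowed_within = windowed_means(d_gs, d_h, width=3.0)
    else:
        windowed_within = pd.DataFrame()

    # RV SD analyses in the respiratory subgroup, plus residual-GS control
    if "rv_sd" in kept:
        resp = kept.dropna(subset=["rv_sd"])
        sess_rv = _session_table(resp, ["gs_fluct", "rv_sd", "scan_hour"])
        for session, chunk in sess_rv.groupby("session"):
            if len(chunk) < 4:
                continue
            fams = chunk["family_id"].to_numpy()
            hours = chunk["scan_hour"].to_numpy()
            res = between_participant_corr(chunk["rv_sd"].to_numpy(), hours,
                                           fams, n_perm=nperm, seed=seed)
            tod_rows.append({"measure": "rv_sd", "level": "between",
                             "session": session, "n": res.n, "r": res.r, "p": res.p})
            resid = regress_covariate(chunk["gs_fluct"].to_numpy(),
                                      chunk["rv_sd"].to_numpy())
            res = between_participant_corr(resid, hours, fams,
                                           n_perm=nperm, seed=seed)
            tod_rows.append({"measure": "gs_fluct_resid_rv", "level": "between",
                             "session": session, "n": res.n, "r": res.r, "p": res.p})

    tod_correlations = pd.DataFrame(tod_rows)
    fits = pd.DataFrame(fit_rows)

    # ------------------------------------------------------------- run effect
    run_rows = []
    for session, chunk in kept.groupby("session"):
        wide = chunk.pivot_table(index=["participant_id", "family_id"],
                                 columns="run", values="gs_fluct").dropna()
        if len(wide) >= 3 and wide.shape[1] >= 2:
            r1, r2 = sorted(c for c in wide.columns)[:2]
            t, p = paired_run_test(wide[r1].to_numpy(), wide[r2].to_numpy(),
                                   wide.index.get_level_values("family_id").to_numpy(),
                                   n_perm=nperm, seed=seed)
            run_rows.append({"session": session, "n": len(wide), "t": t, "p": p})
    run_effects = pd.DataFrame(run_rows)

    # ------------------------------------------------------------ metric grids
    grid_gs = metric_correlation_grid(summaries, target="gs_fluct",
                                      n_perm=nperm, seed=seed)
    grid_tod = metric_correlation_grid(summaries, target="scan_hour",
                                       n_perm=nperm, seed=seed)
    subgroup_tod = gs_tod_by_subgroup(summaries, n_perm=nperm, seed=seed)

    # -------------------------------------------- regional and RSFC analyses
    regional_tod, network_tables, nbs_rows, medz_rows = [], {}, [], []
    for variant, reg_maps, rsfc_maps in (
            ("raw", regional, rsfc_acc),
            ("gsr", regional_gsr, rsfc_gsr_acc)):
        if not reg_maps:
            continue
        sess_keys = sorted({s for (_, s) in reg_maps})
        for session in sess_keys:
            pids = [k for k in reg_maps if k[1] == session]
            ok = kept[kept["session"] == session]["participant_id"].unique()
            pids = [k for k in pids if k[0] in set(ok)]
            if len(pids) < 4:
                continue
            fam_of = dict(zip(manifest["participant_id"], manifest["family_id"]))
            fams = np.array([fam_of[k[0]] for k in pids])
            hours = (kept[kept["session"] == session]
                     .groupby("participant_id")["scan_hour"].mean())
            hvec = hours.loc[[k[0] for k in pids]].to_numpy()

            maps = np.stack([np.mean(reg_maps[k], axis=0) for k in pids])
            r, p = _vector_corr_perm(maps, hvec, fams, nperm, seed)
            rej, _ = fdr_correct(p, q=config.q)
            regional_tod.append(pd.DataFrame({
                "variant": variant, "session": session,
                "region": np.arange(maps.shape[1]), "network": net_labels,
                "r": r, "p": p, "q_sig": rej}))

            stack = np.stack([np.mean(rsfc_maps[k], axis=0) for k in pids])
            edge_r = edgewise_covariate_corr(stack, hvec)
            network_tables[(variant, session)] = network_average(edge_r, net_labels)
            medz_rows.append({"variant": variant, "session": session,
                              "median_abs_z": median_abs_z(edge_r)})
            nbs = network_based_statistic(stack, hvec, families=fams,
                                          n_perm=nperm, seed=seed,
                                          edge_p_thresh=config.nbs_edge_p,
                                          q=config.q)
            nbs_rows.append({
                "variant": variant, "session": session,
                "n_components": len(nbs.components),
                "n_suprathreshold_edges": nbs.n_suprathreshold,
                "largest_component": float(nbs.sizes.max()) if nbs.sizes.size else 0.0,
                "min_p": float(nbs.p_values.min()) if nbs.p_values.size else np.nan,
                "significant": bool(nbs.q_reject.any()),
            })
    regional_tod = (pd.concat(regional_tod, ignore_index=True)
                    if regional_tod else pd.DataFrame())
    nbs_table = pd.DataFrame(nbs_rows)
    medz_table = pd.DataFrame(medz_rows)

    windowed_between = {
        int(session): windowed_means(chunk["gs_fluct_pct"].to_numpy(),
                                     chunk["scan_hour"].to_numpy(), width=1.0)
        for session, chunk in sess.groupby("session")}

    info = {"config_hash": config.config_hash(), "seed": seed,
            "n_permutations": nperm}
    bundle = {
        "info": info, "log": log, "run_metrics": run_metrics,
        "summaries": summaries, "tod_correlations": tod_correlations,
        "run_effects": run_effects, "metric_grid_gs": grid_gs,
        "metric_grid_tod": grid_tod, "subgroup_tod": subgroup_tod,
        "regional_tod": regional_tod, "network_tables": network_tables,
        "median_abs_z": medz_table, "nbs": nbs_table, "fits": fits,
        "windowed_between": windowed_between, "windowed_within": windowed_within,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), overwrite)
    return bundle


def _iter_simulated(cohort: Cohort, config: AnalysisConfig):
    for ctx in cohort.contexts():
        bold, noise = simulate_bold(ctx, cohort.effects, return_noise=True)
        physio = simulate_physio(ctx, cohort.effects) if config.with_physio else None
        motion = simulate_motion(ctx, cohort.effects) if config.with_motion else None
        meta = {"participant_id": ctx.participant_id, "family_id": ctx.family_id,
                "session": ctx.session, "run": ctx.run, "scan_hour": ctx.scan_hour}
        yield meta, bold, noise, physio, motion


def _iter_directory(config: AnalysisConfig):
    cohort_dir = Path(config.cohort_dir)
    manifest = cio.read_manifest(cohort_dir)
    meta_json = json.loads((cohort_dir / "meta.json").read_text())

    def gen():
        for row in manifest.itertuples(index=False):
            bold = cio.read_bold(cohort_dir, row.participant_id, row.session,
                                 row.run, tr_seconds=row.tr_s)
            physio = motion = None
            if config.with_physio:
                try:
                    physio = cio.read_physio(cohort_dir, row.participant_id,
                                             row.session, row.run,
                                             sampling_hz=meta_json["physio_hz"])
                except OSError:
                    physio = None
            if config.with_motion:
                try:
                    motion = cio.read_motion(cohort_dir, row.participant_id,
                                             row.session, row.run)
                except OSError:
                    motion = None
            meta = {"participant_id": row.participant_id,
                    "family_id": row.family_id, "session": int(row.session),
                    "run": int(row.run), "scan_hour": float(row.scan_hour)}
            yield meta, bold, None, physio, motion

    return manifest, gen()


def _write_bundle(bundle: dict, out: Path, overwrite: bool) -> None:
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={bundle['info']['config_hash']} seed={bundle['info']['seed']}\n"

    def write_df(df: pd.DataFrame, name: str) -> None:
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, index=False)

    for name in ("run_metrics", "summaries", "tod_correlations", "run_effects",
                 "metric_grid_gs", "metric_grid_tod", "subgroup_tod",
                 "regional_tod", "median_abs_z", "nbs", "fits",
                 "windowed_within"):
        df = bundle[name]
        if isinstance(df, pd.DataFrame) and len(df):
            write_df(df, name)
    for session, df in bundle["windowed_between"].items():
        write_df(df, f"windowed_between_session{session}")
    for (variant, session), table in bundle["network_tables"].items():
        path = out / f"network_tod_{variant}_session{session}.csv"
        with open(path, "w") as fh:
            fh.write(stamp)
            table.to_csv(fh)
    (out / "bundle_info.json").write_text(
        json.dumps({**bundle["info"], "log": bundle["log"]}, indent=2))
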