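"""Plain-text readers and writers for cohort directories.

Layout of a cohort directory:

* ``manifest.csv`` — participant_id, family_id, session, run,
  scan_start_hhmm, tr_s, n_frames
* ``regions.csv`` — region, network, cortical (shared sidecar)
* ``<pid>_ses<k>_run<j>_bold.tsv`` — tab-separated frames x regions with a
  header row of region labels
* ``<pid>_ses<k>_run<j>_physio.txt`` — 3 whitespace-delimited columns
  (trigger, respiration, pulse) at the physio sampling rate
* ``<pid>_ses<k>_run<j>_motion.txt`` — 6 whitespace-delimited columns
  (trans x,y,z in mm; rot x,y,z in radians)
* ``ground_truth.csv`` — latent per-run truth of the synthetic generator
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, simulate_bold, simulate_motion, simulate_physio
from .physio import PhysioTrace
from .signals import ParcellatedBOLD

__all__ = [
    "hours_to_hhmm",
    "hhmm_to_hours",
    "run_stem",
    "write_cohort",
    "read_manifest",
    "read_regions",
    "read_bold",
    "read_physio",
    "read_motion",
    "write_matrix_csv",
    "read_matrix_csv",
]


def hours_to_hhmm(hour: float) -> str:
    minutes = int(round(hour * 60)) % (24 * 60)
    return f"{minutes // 60:02d}{minutes % 60:02d}"


def hhmm_to_hours(hhmm: str) -> float:
    s = str(hhmm).zfill(4)
    return int(s[:2]) + int(s[2:]) / 60.0


def run_stem(participant_id: str, session: int, run: int) -> str:
    return f"{participant_id}_ses{session}_run{run}"


def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    include_bold: bool = True,
    include_physio: bool = True,
    include_motion: bool = True,
    include_truth: bool = True,
) -> Path:
    """Materialise a simulated cohort as a plain-text directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = cohort.manifest.copy()
    manifest["scan_start_hhmm"] = manifest["scan_hour"].map(hours_to_hhmm)
    cols = ["participant_id", "family_id", "session", "run",
            "scan_start_hhmm", "tr_s", "n_frames"]
    manifest[cols].to_csv(out / "manifest.csv", index=False)

    first_ctx = next(cohort.contexts())
    bold0 = simulate_bold(first_ctx, cohort.effects)
    pd.DataFrame({
        "region": bold0.region_labels,
        "network": bold0.network_labels,
        "cortical": bold0.cortical_mask.astype(int),
    }).to_csv(out / "regions.csv", index=False)
    (out / "meta.json").write_text(json.dumps({
        "physio_hz": cohort.spec.physio_hz,
        "tr_seconds": cohort.spec.tr_seconds,
        "n_frames": cohort.spec.n_frames,
        "seed": cohort.spec.seed,
    }, indent=2))

    for ctx in cohort.contexts():
        stem = run_stem(ctx.participant_id, ctx.session, ctx.run)
        if include_bold:
            bold = simulate_bold(ctx, cohort.effects)
            header = "\t".join(bold.region_labels)
            np.savetxt(out / f"{stem}_bold.tsv", bold.data, fmt="%.4f",
                       delimiter="\t", header=header, comments="")
        if include_physio:
            trace = simulate_physio(ctx, cohort.effects)
            trigger = _frame_triggers(trace, ctx.spec)
            np.savetxt(out / f"{stem}_physio.txt",
                       np.column_stack([trigger, trace.respiration, trace.pulse]),
                       fmt=["%d", "%.6f", "%.6f"])
        if include_motion:
            np.savetxt(out / f"{stem}_motion.txt",
                       simulate_motion(ctx, cohort.effects), fmt="%.6f")

    if include_truth:
        # synthetic latent truth; not part of the emulated acquisition
        cohort.manifest.to_csv(out / "ground_truth.csv", index=False)
        cohort.participants.to_csv(out / "participants_truth.csv", index=False)
    return out


def _frame_triggers(trace: PhysioTrace, spec: CohortSpec) -> np.ndarray:
    trigger = np.zeros(trace.respiration.size, dtype=int)
    onsets = (np.arange(spec.n_frames) * spec.tr_seconds * spec.physio_hz).round()
    onsets = onsets[onsets < trigger.size].astype(int)
    trigger[onsets] = 1
    return trigger


def read_manifest(cohort_dir: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(cohort_dir) / "manifest.csv",
                     dtype={"scan_start_hhmm": str})
    df["scan_hour"] = df["scan_start_hhmm"].map(hhmm_to_hours)
    return df


def read_regions(cohort_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(cohort_dir) / "regions.csv")


def read_bold(cohort_dir: str | Path, participant_id: str, session: int,
              run: int, tr_seconds: float) -> ParcellatedBOLD:
    path = Path(cohort_dir) / f"{run_stem(participant_id, session, run)}_bold.tsv"
    table = pd.read_csv(path, sep="\t")
    regions = read_regions(cohort_dir)
    return ParcellatedBOLD(
        data=table.to_numpy(float),
        region_labels=list(table.columns),
        network_labels=list(regions["network"]),
        cortical_mask=regions["cortical"].to_numpy(bool),
        tr_seconds=tr_seconds,
    )


def read_physio(cohort_dir: str | Path, participant_id: str, session: int,
                run: int, sampling_hz: float) -> PhysioTrace:
    path = Path(cohort_dir) / f"{run_stem(participant_id, session, run)}_physio.txt"
    data = np.loadtxt(path)
    return PhysioTrace(sampling_hz=sampling_hz, respiration=data[:, 1],
                       pulse=data[:, 2])


def read_motion(cohort_dir: str | Path, participant_id: str, session: int,
                run: int) -> np.ndarray:
    path = Path(cohort_dir) / f"{run_stem(participant_id, session, run)}_motion.txt"
    return np.loadtxt(path)


def write_matrix_csv(matrix: np.ndarray, labels, path: str | Path) -> None:
    """Serialise a labelled square matrix as CSV with header row/column."""
    pd.DataFrame(np.asarray(matrix), index=labels, columns=labels).to_csv(path)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
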