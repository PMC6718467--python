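"""Delimited-text readers and writers for cohorts and results.

Everything is plain text: per-subject time-series matrices as TSV, event
tables as TSV (onset_s, duration_s, condition), the ROI table and cohort
manifest as CSV, ground truth as JSON, connectivity matrices as square TSV
plus an edge list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rest_fc import ConnectivityMatrix
from .synthetic import Cohort, GroundTruth, RoiSet, SubjectRecord
from .task_glm import TaskDesign

__all__ = [
    "write_cohort", "read_cohort",
    "write_events", "read_events",
    "write_roi_table", "read_roi_table",
    "write_fc", "read_matrix",
    "write_group_inference",
    "write_measures_table",
]


def _write_matrix(path: Path, M: np.ndarray) -> None:
    np.savetxt(path, np.asarray(M), delimiter="\t", fmt="%.10g")


def read_matrix(path) -> np.ndarray:
    M = np.loadtxt(path, delimiter="\t")
    if M.ndim == 1:  # files are written time-by-columns; 1-D means one column
        M = M[:, None]
    return M


def write_events(path, design: TaskDesign) -> None:
    df = pd.DataFrame(design.events, columns=["onset_s", "duration_s", "condition"])
    df.to_csv(path, sep="\t", index=False)


def read_events(path, scheme: str, run_boundaries=None) -> TaskDesign:
    df = pd.read_csv(path, sep="\t")
    events = [(float(o), float(d), str(c))
              for o, d, c in zip(df["onset_s"], df["duration_s"], df["condition"])]
    return TaskDesign(events=events, scheme=scheme,
                      run_boundaries=list(run_boundaries or [0]))


def write_roi_table(path, roi_set: RoiSet) -> None:
    pd.DataFrame({
        "roi_id": np.arange(roi_set.n_roi),
        "x": roi_set.coordinates[:, 0],
        "y": roi_set.coordinates[:, 1],
        "z": roi_set.coordinates[:, 2],
        "network": roi_set.network_labels,
        "radius_mm": roi_set.radius_mm,
    }).to_csv(path, index=False)


def read_roi_table(path) -> RoiSet:
    df = pd.read_csv(path)
    return RoiSet(
        coordinates=df[["x", "y", "z"]].to_numpy(float),
        radius_mm=float(df["radius_mm"].iloc[0]) if "radius_mm" in df else 6.0,
        network_labels=df["network"].to_numpy(str),
    )


def write_cohort(out_dir, cohort: Cohort) -> None:
    """Cohort as per-subject TSVs + manifest.csv + roi_table.csv (+ truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_roi_table(out / "roi_table.csv", cohort.roi_set)
    rows = []
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        _write_matrix(sdir / "rest_ts.tsv", s.rest_ts)
        _write_matrix(sdir / "motion.tsv", s.motion)
        _write_matrix(sdir / "wm_signals.tsv", s.wm_signals)
        _write_matrix(sdir / "csf_signals.tsv", s.csf_signals)
        _write_matrix(sdir / "task_ts.tsv", s.task_ts)
        write_events(sdir / "events.tsv", s.design)
        rows.append({
            "subject_id": s.subject_id, "cohort": s.cohort,
            "tr_rest": s.tr_rest, "tr_task": s.tr_task,
            "scheme": s.design.scheme,
            "run_boundaries": ";".join(map(str, s.design.run_boundaries)),
            "path": s.subject_id,
        })
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    gt = cohort.ground_truth
    if gt is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump({
                "true_edge_weights": {k: v.tolist() for k, v in gt.true_edge_weights.items()},
                "noise_sd_target": gt.noise_sd_target,
                "support_edges": gt.support_edges.tolist(),
                "support_network": gt.support_network,
                "true_task_betas": gt.true_task_betas,
            }, fh)


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    roi_set = read_roi_table(src / "roi_table.csv")
    manifest = pd.read_csv(src / "manifest.csv")
    subjects = []
    for _, row in manifest.iterrows():
        sdir = src / str(row["path"])
        bounds = [int(b) for b in str(row["run_boundaries"]).split(";")]
        design = read_events(sdir / "events.tsv", str(row["scheme"]), bounds)
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]), cohort=int(row["cohort"]),
            rest_ts=read_matrix(sdir / "rest_ts.tsv"), tr_rest=float(row["tr_rest"]),
            motion=read_matrix(sdir / "motion.tsv"),
            wm_signals=read_matrix(sdir / "wm_signals.tsv"),
            csf_signals=read_matrix(sdir / "csf_signals.tsv"),
            task_ts=read_matrix(sdir / "task_ts.tsv"),
            tr_task=float(row["tr_task"]), design=design,
        ))
    gt = None
    gt_path = src / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            raw = json.load(fh)
        gt = GroundTruth(
            true_edge_weights={k: np.asarray(v) for k, v in raw["true_edge_weights"].items()},
            noise_sd_target=raw["noise_sd_target"],
            rest_cov={}, true_task_betas=raw.get("true_task_betas", {}),
            support_edges=np.asarray(raw.get("support_edges", []), dtype=int),
            support_network=raw.get("support_network", "DM"),
        )
    return Cohort(subjects=subjects, roi_set=roi_set, ground_truth=gt)


def write_fc(out_dir, name: str, C: ConnectivityMatrix) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_matrix(out / f"{name}_fc.tsv", C.r)
    iu = np.triu_indices(C.n_roi, k=1)
    pd.DataFrame({"roi_i": iu[0], "roi_j": iu[1], "r": C.r[iu]}).to_csv(
        out / f"{name}_edges.csv", index=False
    )


def write_group_inference(path, inference) -> None:
    """Group FC inference as an edge table (roi_i, roi_j, mean_r, p_fwe)."""
    n = inference.mean_r.shape[0]
    iu = np.triu_indices(n, k=1)
    pd.DataFrame({
        "roi_i": iu[0], "roi_j": iu[1],
        "mean_r": inference.mean_r[iu],
        "p_fwe": inference.p_fwe[iu],
        "significant": inference.sig_mask[iu],
    }).to_csv(path, index=False)


def write_measures_table(path, subject_ids, measures_per_subject) -> None:
    """Per-subject measures table (subject_id, sensitivity, maximal, average, intercept)."""
    rows = []
    for sid, m in zip(subject_ids, measures_per_subject):
        rows.append({
            "subject_id": sid,
            "sensitivity": float(np.asarray(m.sensitivity).ravel()[0]),
            "maximal": float(np.asarray(m.maximal).ravel()[0]),
            "average": float(np.asarray(m.average).ravel()[0]),
            "intercept": float(np.asarray(m.intercept).ravel()[0]),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
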