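"""Readers and writers for the formats the tracker touches.

Detections and tracks travel as CSV, images as multi-page TIFF, run
configuration as YAML, filter checkpoints and estimator reports as JSON, and
lineage as Cell Tracking Challenge-style ``L B E P`` text.  Frames are
1-based throughout; measurement indices within a frame are 1-based with 0
reserved for miss-detection.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .estimator import SmoothedTrajectory
from .filter import GLMBDensity, GLMBHypothesis, Scan, Track
from .models import GaussianComponent, Label
from .scenarios import GroundTruth, TruthTrack

__all__ = [
    "read_detection_scans",
    "write_detection_scans",
    "write_tracks",
    "read_tracks_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_images",
    "read_images",
    "write_metrics_csv",
    "write_estimator_report",
    "save_checkpoint",
    "load_checkpoint",
    "load_yaml_config",
]

_DIALECTS = {
    "cartesian": ("x", "y"),
    "polar": ("theta", "range"),
}


def read_detection_scans(path, dialect: Optional[str] = None) -> List[Scan]:
    """Read per-frame detections from CSV (``frame,x,y`` or
    ``frame,theta,range``) or the JSON equivalent.

    Returns one :class:`Scan` per frame from 1 to the maximum frame, with
    empty frames filled in; within-frame ordering is preserved (association
    histories index measurements in this order)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = pd.DataFrame(payload["detections"])
    else:
        rows = pd.read_csv(path)
    if rows.empty and not set(rows.columns):
        raise ValueError(f"{path}: no header found")
    cols = [c.strip().lower() for c in rows.columns]
    rows.columns = cols
    if dialect is None:
        for name, (cx, cy) in _DIALECTS.items():
            if cx in cols and cy in cols:
                dialect = name
                break
    if dialect is None or dialect not in _DIALECTS:
        raise ValueError(
            f"{path}: expected columns frame,x,y or frame,theta,range; got {cols}"
        )
    cx, cy = _DIALECTS[dialect]
    for col in ("frame", cx, cy):
        if col not in cols:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(rows):
        bad = rows[["frame", cx, cy]].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
        if bad.any():
            raise ValueError(f"{path}: non-numeric value at row {int(np.flatnonzero(bad)[0]) + 2}")
        rows["frame"] = rows["frame"].astype(int)
        if (rows["frame"] < 1).any():
            bad_row = int(np.flatnonzero(rows["frame"] < 1)[0]) + 2
            raise ValueError(f"{path}: negative or zero frame at row {bad_row}")
    max_frame = int(rows["frame"].max()) if len(rows) else 0
    scans = []
    for k in range(1, max_frame + 1):
        sub = rows[rows["frame"] == k]
        Z = sub[[cx, cy]].to_numpy(dtype=float) if len(sub) else np.zeros((0, 2))
        scans.append(Scan(frame=k, Z=Z))
    return scans


def write_detection_scans(scans: Sequence[Scan], path, dialect: str = "cartesian") -> None:
    cx, cy = _DIALECTS[dialect]
    recs = []
    for s in scans:
        for z in s.Z:
            recs.append({"frame": s.frame, cx: z[0], cy: z[1]})
    pd.DataFrame(recs, columns=["frame", cx, cy]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


def _assign_track_ids(trajectories: Sequence[SmoothedTrajectory]) -> Dict[Label, int]:
    """Deterministic positive integer ids in label sort order."""
    labels = sorted(t.label for t in trajectories)
    return {lab: i + 1 for i, lab in enumerate(labels)}


def write_tracks(
    trajectories: Sequence[SmoothedTrajectory], path, format: str = "csv"
) -> None:
    """Write smoothed trajectories.

    ``csv``: rows (track_id, parent_id, frame, x, y, state...); ``ctc``: one
    ``L B E P`` line per track (label, begin frame, end frame, parent label
    or 0) in Cell Tracking Challenge lineage style.  Refuses fragmented
    input (a label appearing in more than one trajectory)."""
    labels = [t.label for t in trajectories]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})[0]
        raise ValueError(f"fragmented trajectory set: label {dup} appears more than once")
    ids = _assign_track_ids(trajectories)
    if format == "ctc":
        lines = []
        for t in sorted(trajectories, key=lambda t: ids[t.label]):
            parent = ids.get(t.parent, 0) if t.parent is not None else 0
            lines.append(f"{ids[t.label]} {t.birth_frame} {t.last_frame} {parent}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    if format != "csv":
        raise ValueError(f"unknown track format {format!r}")
    recs = []
    for t in sorted(trajectories, key=lambda t: ids[t.label]):
        parent = ids.get(t.parent, 0) if t.parent is not None else 0
        for i, comp in enumerate(t.components):
            rec = {
                "track_id": ids[t.label],
                "parent_id": parent,
                "frame": t.birth_frame + i,
                "x": comp.mean[0],
                "y": comp.mean[1],
                "label": str(t.label),
            }
            for d in range(2, comp.dim):
                rec[f"s{d}"] = comp.mean[d]
            recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)


def read_tracks_csv(path) -> Dict[int, Dict[int, np.ndarray]]:
    """Track CSV back to {track_id: {frame: position}} (metrics-ready)."""
    df = pd.read_csv(path)
    out: Dict[int, Dict[int, np.ndarray]] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["track_id"]), {})[int(row["frame"])] = np.array(
            [row["x"], row["y"]]
        )
    return out


def write_truth_csv(truth: GroundTruth, path) -> None:
    recs = []
    for t in truth.tracks:
        for i in range(t.states.shape[0]):
            rec = {
                "label": t.track_id,
                "parent": t.parent_id,
                "frame": t.birth + i,
                "x": t.states[i, 0],
                "y": t.states[i, 1],
            }
            for d in range(2, t.states.shape[1]):
                rec[f"s{d}"] = t.states[i, d]
            recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)


def read_truth_csv(path) -> GroundTruth:
    df = pd.read_csv(path)
    scols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    tracks = []
    for tid, sub in df.groupby("label"):
        sub = sub.sort_values("frame")
        states = sub[["x", "y"] + scols].to_numpy(dtype=float)
        tracks.append(
            TruthTrack(
                track_id=int(tid),
                parent_id=int(sub["parent"].iloc[0]),
                birth=int(sub["frame"].iloc[0]),
                states=states,
            )
        )
    K = int(df["frame"].max()) if len(df) else 0
    return GroundTruth(tracks=tracks, K=K)


# ---------------------------------------------------------------------------
# Images, metrics, reports
# ---------------------------------------------------------------------------


def write_images(images: Sequence[np.ndarray], path) -> None:
    tifffile.imwrite(path, np.stack(images).astype(np.float32), photometric="minisblack")


def read_images(path) -> List[np.ndarray]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return [arr]
    return [a for a in arr]


def write_metrics_csv(rows: Iterable[dict], path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False)


def write_estimator_report(result, path) -> None:
    """Per-frame cardinality sequence, pruned-track count and per-track
    summaries as JSON."""
    ids = _assign_track_ids(result.trajectories)
    report = {
        "mode": result.mode,
        "map_cardinality": list(map(int, result.map_cardinalities)),
        "pruned_track_count": int(result.pruned_count),
        "n_tracks": len(result.trajectories),
        "tracks": [
            {
                "track_id": ids[t.label],
                "label": str(t.label),
                "parent_id": ids.get(t.parent, 0) if t.parent is not None else 0,
                "birth_frame": int(t.birth_frame),
                "end_frame": int(t.last_frame),
                "length": len(t.components),
            }
            for t in result.trajectories
        ],
        "frames": [
            {
                "frame": lg.frame,
                "n_meas": lg.n_meas,
                "n_hyp_pre": lg.n_hyp_pre,
                "n_hyp_post": lg.n_hyp_post,
                "map_cardinality": lg.map_cardinality,
                "effective_n_hyp": lg.effective_n_hyp,
            }
            for lg in result.logs
        ],
    }
    Path(path).write_text(json.dumps(report, indent=2))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def _label_to_obj(label: Label):
    out = {"time": label.time, "index": label.index}
    if label.parent is not None:
        out["parent"] = _label_to_obj(label.parent)
    return out


def _label_from_obj(obj) -> Label:
    parent = _label_from_obj(obj["parent"]) if "parent" in obj else None
    return Label(time=obj["time"], index=obj["index"], parent=parent)


def save_checkpoint(glmb: GLMBDensity, path) -> None:
    """Serialize a GLMB density (labels, log-weights, per-label mean/cov and
    association histories); log-weights round-trip exactly via float hex."""
    payload = {
        "frame": glmb.frame,
        "hypotheses": [
            {
                "log_weight": h.log_weight.hex()
                if isinstance(h.log_weight, float)
                else float(h.log_weight).hex(),
                "tracks": [
                    {
                        "label": _label_to_obj(t.label),
                        "birth_frame": t.birth_frame,
                        "history": list(t.history),
                        "mean": t.comp.mean.tolist(),
                        "cov": t.comp.cov.tolist(),
                        "birth_mean": t.birth_state.mean.tolist(),
                        "birth_cov": t.birth_state.cov.tolist(),
                    }
                    for t in h.tracks
                ],
            }
            for h in glmb.hypotheses
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> GLMBDensity:
    payload = json.loads(Path(path).read_text())
    hyps = []
    for h in payload["hypotheses"]:
        tracks = tuple(
            Track(
                label=_label_from_obj(t["label"]),
                birth_frame=t["birth_frame"],
                birth_state=GaussianComponent(
                    np.array(t["birth_mean"]), np.array(t["birth_cov"])
                ),
                history=tuple(t["history"]),
                comp=GaussianComponent(np.array(t["mean"]), np.array(t["cov"])),
            )
            for t in h["tracks"]
        )
        hyps.append(GLMBHypothesis(float.fromhex(h["log_weight"]), tracks))
    return GLMBDensity(hyps, payload["frame"])


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
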