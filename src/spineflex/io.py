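"""File formats: keypoint CSV, COCO keypoint JSON, mocap CSV, labels, features.

All formats are plain text. The keypoint CSV has one row per frame with
columns ``participant_id, frame, ankle_x, ankle_y, hip_x, hip_y, neck_x,
neck_y`` and optional ``*_conf`` confidence columns. The mocap CSV is
TRC-like: ``frame`` followed by ``<MARKER>_X/_Y/_Z`` triplets for C7, L4,
LASIS, RASIS, LPSIS, RPSIS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import MOCAP_MARKERS, KeypointTrajectory, MocapTrial
from .repetitions import ANGLE_FEATURE_NAMES

_KEYPOINTS = ("ankle", "hip", "neck")

# COCO-17 keypoint indices used to derive the three landmarks
_COCO_PAIRS = {
    "neck": (5, 6),  # left/right shoulder
    "hip": (11, 12),  # left/right hip
    "ankle": (15, 16),  # left/right ankle
}


class ParseError(ValueError):
    """A data file could not be interpreted."""


def write_keypoints_csv(traj: KeypointTrajectory, path: str | Path) -> None:
    n = traj.n_frames
    data = {"participant_id": [traj.participant_id] * n, "frame": np.arange(n)}
    for name in _KEYPOINTS:
        arr = getattr(traj, name)
        data[f"{name}_x"] = arr[:, 0]
        data[f"{name}_y"] = arr[:, 1]
    if traj.confidence:
        for name, conf in traj.confidence.items():
            data[f"{name}_conf"] = conf
    pd.DataFrame(data).to_csv(path, index=False)


def read_keypoints_csv(path: str | Path, fps: float = 30.0) -> KeypointTrajectory:
    df = pd.read_csv(path)
    required = ["participant_id", "frame"] + [
        f"{k}_{ax}" for k in _KEYPOINTS for ax in ("x", "y")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"keypoint file {path}: missing columns {missing}")
    df = df.sort_values("frame")
    pids = df["participant_id"].astype(str).unique()
    if len(pids) != 1:
        raise ParseError(f"keypoint file {path}: expected one participant, got {pids}")
    conf = {
        k: df[f"{k}_conf"].to_numpy(float)
        for k in _KEYPOINTS
        if f"{k}_conf" in df.columns
    }
    return KeypointTrajectory(
        participant_id=pids[0],
        fps=fps,
        ankle=df[["ankle_x", "ankle_y"]].to_numpy(float),
        hip=df[["hip_x", "hip_y"]].to_numpy(float),
        neck=df[["neck_x", "neck_y"]].to_numpy(float),
        confidence=conf or None,
    )


def trajectory_from_coco(
    frames: list,
    participant_id: str,
    fps: float = 30.0,
    confidence_threshold: float = 0.3,
) -> KeypointTrajectory:
    """Adapt per-frame COCO-17 keypoint arrays to the three-landmark format.

    Each frame is a flat 51-vector (or 17×3 array) of x, y, confidence in
    COCO order. The neck is the shoulder midpoint, the hip the hip-centre
    midpoint and the ankle the ankle midpoint; when one side's confidence
    falls below ``confidence_threshold`` the other side is used alone, and
    a frame where both sides fail raises :class:`ParseError`.
    """
    out = {k: [] for k in _KEYPOINTS}
    conf_out = {k: [] for k in _KEYPOINTS}
    for i, frame in enumerate(frames):
        kp = np.asarray(frame, dtype=float).reshape(17, 3)
        for name, (li, ri) in _COCO_PAIRS.items():
            lx, ly, lc = kp[li]
            rx, ry, rc = kp[ri]
            ok_l, ok_r = lc >= confidence_threshold, rc >= confidence_threshold
            if ok_l and ok_r:
                pt, c = ((lx + rx) / 2, (ly + ry) / 2), (lc + rc) / 2
            elif ok_l:
                pt, c = (lx, ly), lc
            elif ok_r:
                pt, c = (rx, ry), rc
            else:
                raise ParseError(
                    f"frame {i}: both sides of {name} below confidence "
                    f"threshold {confidence_threshold}"
                )
            out[name].append(pt)
            conf_out[name].append(c)
    return KeypointTrajectory(
        participant_id=participant_id,
        fps=fps,
        ankle=np.asarray(out["ankle"]),
        hip=np.asarray(out["hip"]),
        neck=np.asarray(out["neck"]),
        confidence={k: np.asarray(v) for k, v in conf_out.items()},
    )


def read_coco_json(path: str | Path, participant_id: str | None = None,
                   fps: float = 30.0, confidence_threshold: float = 0.3
                   ) -> KeypointTrajectory:
    doc = json.loads(Path(path).read_text())
    if isinstance(doc, dict):
        frames = doc.get("frames")
        participant_id = participant_id or doc.get("participant_id")
        fps = doc.get("fps", fps)
    else:
        frames = doc
    if not isinstance(frames, list) or not frames:
        raise ParseError(f"COCO file {path}: no frames found")
    return trajectory_from_coco(
        [f["keypoints"] if isinstance(f, dict) else f for f in frames],
        participant_id=participant_id or Path(path).stem,
        fps=fps,
        confidence_threshold=confidence_threshold,
    )


def write_mocap_csv(trial: MocapTrial, path: str | Path) -> None:
    n = trial.n_frames
    data = {"frame": np.arange(n)}
    for m in MOCAP_MARKERS:
        for ax, col in enumerate(("X", "Y", "Z")):
            data[f"{m}_{col}"] = trial.markers[m][:, ax]
    pd.DataFrame(data).to_csv(path, index=False)


def read_mocap_csv(
    path: str | Path,
    participant_id: str | None = None,
    fps: float = 120.0,
    vertical_axis: int = 1,
    units: str = "m",
) -> MocapTrial:
    df = pd.read_csv(path).sort_values("frame")
    markers = {}
    for m in MOCAP_MARKERS:
        cols = [f"{m}_{c}" for c in ("X", "Y", "Z")]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"mocap file {path}: missing columns {missing}")
        markers[m] = df[cols].to_numpy(float)
    return MocapTrial(
        participant_id=participant_id or Path(path).stem,
        markers=markers,
        fps=fps,
        vertical_axis=vertical_axis,
        units=units,
    )


def write_labels_csv(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"participant_id": list(labels), "label": list(labels.values())}
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    for col in ("participant_id", "label"):
        if col not in df.columns:
            raise ParseError(f"labels file {path}: missing column {col!r}")
    bad = sorted(set(df["label"]) - {"MI", "MCI"})
    if bad:
        raise ParseError(f"labels file {path}: unknown labels {bad}")
    return dict(zip(df["participant_id"].astype(str), df["label"]))


def write_features_csv(features: dict[str, np.ndarray], path: str | Path) -> None:
    """Tidy per-participant kinematic features (fixed Table-order columns)."""
    rows = [
        {"participant_id": pid, **dict(zip(ANGLE_FEATURE_NAMES, vec))}
        for pid, vec in features.items()
    ]
    pd.DataFrame(rows, columns=["participant_id", *ANGLE_FEATURE_NAMES]).to_csv(
        path, index=False
    )


def read_features_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", *ANGLE_FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ParseError(f"features file {path}: missing columns {missing}")
    return {
        str(row["participant_id"]): np.array(
            [float(row[c]) for c in ANGLE_FEATURE_NAMES]
        )
        for _, row in df.iterrows()
    }
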