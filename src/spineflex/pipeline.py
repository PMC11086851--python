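"""End-to-end assembly: trajectories → features → design matrices.

Convenience layer used by the CLI, the evaluation protocol and the tests;
each step simply delegates to the corresponding module.
"""

from __future__ import annotations

import numpy as np

from .kinematics import KeypointTrajectory, angle_waveform, smooth_waveform
from .proms import PROMS
from .repetitions import AngleFeatures, extract_angle_features
from .synthetic import Cohort


def trajectory_features(
    traj: KeypointTrajectory, window_frames: int = 30
) -> AngleFeatures:
    """Angle waveform → 1 s smoothing → repetition segmentation → 9 features."""
    wave = smooth_waveform(angle_waveform(traj), window_frames=window_frames)
    return extract_angle_features(wave)


def cohort_design_matrices(
    cohort: Cohort, window_frames: int = 30
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Extract (angle_X, proms_X, y, participant_ids) from a synthetic cohort."""
    angle_rows, proms_rows, ys, pids = [], [], [], []
    for p in cohort.participants:
        angle_rows.append(trajectory_features(p.trajectory, window_frames).as_array())
        proms_rows.append(p.proms.as_array())
        ys.append(p.y)
        pids.append(p.participant_id)
    return (
        np.vstack(angle_rows),
        np.vstack(proms_rows),
        np.array(ys, dtype=int),
        pids,
    )


def design_matrices_from_tables(
    features: dict[str, np.ndarray],
    proms: dict[str, PROMS],
    labels: dict[str, str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Align per-participant feature, PROMs and label tables by id."""
    pids = sorted(features)
    missing_proms = [p for p in pids if p not in proms]
    missing_labels = [p for p in pids if p not in labels]
    if missing_proms:
        raise ValueError(f"participants missing from PROMs table: {missing_proms}")
    if missing_labels:
        raise ValueError(f"participants missing from labels table: {missing_labels}")
    angle_X = np.vstack([features[p] for p in pids])
    proms_X = np.vstack([proms[p].as_array() for p in pids])
    y = np.array([1 if labels[p] == "MI" else 0 for p in pids], dtype=int)
    return angle_X, proms_X, y, pids
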