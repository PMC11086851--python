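"""Spine-flexion angle kinematics from 2-D pose keypoints and 3-D mocap markers.

The spine-flexion angle θ is the angle at the hip between the hip→neck and
hip→ankle segments, obtained by the law of cosines over the three pairwise
Euclidean distances hip–neck (hn), ankle–hip (ah) and ankle–neck (an):

    θ = arccos((hn² + ah² − an²) / (2·hn·ah))

θ ≈ 180° in relaxed standing and decreases as the trunk flexes forward.
Because θ depends only on distances it is invariant under uniform scaling,
rotation, translation and reflection of the input points, so pixel
coordinates from a video pose estimator need no calibration and image
y-down conventions need no correction.

Motion-capture trials are mapped onto the same construction: the neck is
replaced by the C7 marker, the hip by the centroid of the four pelvic
markers, and the ankle by a *virtual ankle* — the L4 marker with its
vertical coordinate set to zero — so that pose- and mocap-derived angle
waveforms are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MOCAP_MARKERS = ("C7", "L4", "LASIS", "RASIS", "LPSIS", "RPSIS")
PELVIC_MARKERS = ("LASIS", "RASIS", "LPSIS", "RPSIS")


class DegenerateGeometryError(ValueError):
    """Two keypoints that must be distinct coincide (zero segment length)."""


class FpsMismatchError(ValueError):
    """Waveforms sampled at different rates were compared without resampling."""


@dataclass
class KeypointTrajectory:
    """Per-frame sagittal 2-D positions of the ankle, hip and neck keypoints.

    Coordinates are in pixels, frame order is time order. ``confidence`` is an
    optional per-keypoint detector confidence in [0, 1].
    """

    participant_id: str
    fps: float
    ankle: np.ndarray  # (n, 2)
    hip: np.ndarray
    neck: np.ndarray
    confidence: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        for name in ("ankle", "hip", "neck"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must have shape (n, 2), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coordinates in {name}")
            setattr(self, name, arr)
        if not (len(self.ankle) == len(self.hip) == len(self.neck)):
            raise ValueError("ankle/hip/neck must have equal frame counts")

    @property
    def n_frames(self) -> int:
        return len(self.ankle)


@dataclass
class MocapTrial:
    """One optical motion-capture trial: 3-D marker positions at 120 Hz.

    ``markers`` maps each of C7, L4, LASIS, RASIS, LPSIS, RPSIS to an (n, 3)
    array in lab units; ``vertical_axis`` names the axis (0, 1 or 2) that is
    vertical with zero at floor level.
    """

    participant_id: str
    markers: dict[str, np.ndarray]
    fps: float = 120.0
    vertical_axis: int = 1
    units: str = "m"

    def __post_init__(self) -> None:
        missing = [m for m in MOCAP_MARKERS if m not in self.markers]
        if missing:
            raise ValueError(f"missing mocap markers: {missing}")
        n = None
        for name in MOCAP_MARKERS:
            arr = np.asarray(self.markers[name], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name} must have shape (n, 3)")
            bad = np.nonzero(~np.all(np.isfinite(arr), axis=1))[0]
            if bad.size:
                raise ValueError(
                    f"marker {name} has gaps (non-finite frames) at {bad.tolist()[:10]}"
                )
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError("all markers must have equal frame counts")
            self.markers[name] = arr
        if self.vertical_axis not in (0, 1, 2):
            raise ValueError("vertical_axis must be 0, 1 or 2")

    @property
    def n_frames(self) -> int:
        return len(self.markers["C7"])


@dataclass
class AngleWaveform:
    """Per-frame spine-flexion angle θ in degrees."""

    theta: np.ndarray
    fps: float
    smoothed: bool = False
    source: str = "pose"  # "pose" | "mocap"
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1:
            raise ValueError("theta must be one-dimensional")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.theta.size and not (
            np.all(self.theta > 0) and np.all(self.theta <= 180)
        ):
            raise ValueError("theta values must lie in (0, 180] degrees")

    def __len__(self) -> int:
        return self.theta.size

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.fps if len(self) else 0.0


def spine_flexion_angle(ankle, hip, neck) -> float:
    """Angle θ in degrees at the hip vertex between hip→neck and hip→ankle.

    Accepts 2-D or 3-D points. Raises :class:`DegenerateGeometryError` when
    hip/neck or ankle/hip coincide.
    """
    ankle = np.asarray(ankle, dtype=float)
    hip = np.asarray(hip, dtype=float)
    neck = np.asarray(neck, dtype=float)
    hn = float(np.linalg.norm(neck - hip))
    ah = float(np.linalg.norm(hip - ankle))
    an = float(np.linalg.norm(neck - ankle))
    if hn == 0.0:
        raise DegenerateGeometryError("hip and neck coincide (hn = 0)")
    if ah == 0.0:
        raise DegenerateGeometryError("ankle and hip coincide (ah = 0)")
    cos_theta = (hn**2 + ah**2 - an**2) / (2.0 * hn * ah)
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))


def _angles_from_points(ankle: np.ndarray, hip: np.ndarray, neck: np.ndarray) -> np.ndarray:
    """Vectorised law-of-cosines angle over (n, d) point arrays; degrees."""
    hn = np.linalg.norm(neck - hip, axis=1)
    ah = np.linalg.norm(hip - ankle, axis=1)
    an = np.linalg.norm(neck - ankle, axis=1)
    for name, seg in (("hip/neck", hn), ("ankle/hip", ah)):
        bad = np.nonzero(seg == 0.0)[0]
        if bad.size:
            raise DegenerateGeometryError(
                f"coincident {name} keypoints at frame {int(bad[0])}"
            )
    cos_theta = (hn**2 + ah**2 - an**2) / (2.0 * hn * ah)
    return np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))


def angle_waveform(traj: KeypointTrajectory) -> AngleWaveform:
    """Convert a keypoint trajectory into the per-frame flexion-angle waveform."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory: no frames to convert")
    theta = _angles_from_points(traj.ankle, traj.hip, traj.neck)
    return AngleWaveform(
        theta=theta, fps=traj.fps, smoothed=False, source="pose",
        participant_id=traj.participant_id,
    )


def smooth_waveform(wave: AngleWaveform, window_frames: int = 30) -> AngleWaveform:
    """Centered moving average over ``window_frames`` (1 s of video at 30 fps).

    Edge frames use a window shrunk to the available samples
    (``min_periods=1``), so length is preserved and the output range never
    exceeds the input range.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if len(wave) < window_frames:
        raise ValueError(
            f"waveform length {len(wave)} shorter than smoothing window {window_frames}"
        )
    sm = (
        pd.Series(wave.theta)
        .rolling(window=window_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(wave, theta=sm, smoothed=True)


def mocap_spine_angle(trial: MocapTrial) -> AngleWaveform:
    """Spine-flexion angle waveform from a mocap trial.

    neck := C7; hip := centroid of the four pelvic markers; ankle := virtual
    ankle vA, the L4 marker with its vertical coordinate set to zero. θ is
    then the same law-of-cosines angle over 3-D Euclidean distances.
    """
    neck = trial.markers["C7"]
    hip = np.mean([trial.markers[m] for m in PELVIC_MARKERS], axis=0)
    v_ankle = trial.markers["L4"].copy()
    v_ankle[:, trial.vertical_axis] = 0.0
    theta = _angles_from_points(v_ankle, hip, neck)
    return AngleWaveform(
        theta=theta, fps=trial.fps, smoothed=False, source="mocap",
        participant_id=trial.participant_id,
    )


def resample_waveform(wave: AngleWaveform, target_fps: float) -> AngleWaveform:
    """Linear time-interpolation of the waveform onto a ``target_fps`` grid."""
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    if len(wave) == 0:
        raise ValueError("cannot resample an empty waveform")
    duration = wave.duration_s
    n_out = int(np.floor(duration * target_fps)) + 1
    t_out = np.arange(n_out) / target_fps
    t_in = np.arange(len(wave)) / wave.fps
    theta = np.interp(t_out, t_in, wave.theta)
    return replace(wave, theta=theta, fps=float(target_fps))


def waveform_mse(a: AngleWaveform, b: AngleWaveform) -> float:
    """Mean squared per-frame difference between two angle waveforms (deg²).

    Both waveforms must share the same frame rate (resample first); lengths
    may differ by at most two frames and are truncated to the common length.
    """
    if a.fps != b.fps:
        raise FpsMismatchError(
            f"fps mismatch ({a.fps} vs {b.fps}): resample one waveform first"
        )
    if abs(len(a) - len(b)) > 2:
        raise ValueError(
            f"waveform lengths differ by more than 2 frames ({len(a)} vs {len(b)})"
        )
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("cannot compare empty waveforms")
    diff = a.theta[:n] - b.theta[:n]
    return float(np.mean(diff**2))
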