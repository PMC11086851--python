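"""Repetition segmentation and the nine kinematic features of a flexion trial.

Full-flexion events are the minima of the smoothed angle waveform. They are
found by negating the signal and applying continuous-wavelet-transform ridge
peak detection (scipy's ``find_peaks_cwt``), with widths spanning plausible
flexion cadences, then snapping each candidate to the true local minimum of
the waveform in its neighbourhood. Repetition time tr_i is the frame count
between consecutive minima; depth_i is θ at each minimum.

The nine features, in the fixed order downstream subset masks rely on:

    1. variance of θ over all frames (deg²)
    2. standard deviation of θ (deg)
    3. minimum of θ — full spine-flexion angle (deg)
    4. range of θ (deg)
    5. maximum of θ — spine standing angle (deg)
    6. mean repetition time (frames)
    7. variance of repetition time (frames²)
    8. variance of flexion depth (deg²)
    9. movement stability: range of the second half of the waveform minus
       range of the first half (deg)

All variances are sample variances (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks_cwt

from .kinematics import AngleWaveform

ANGLE_FEATURE_NAMES = (
    "variance",
    "std_dev",
    "min_angle",
    "range",
    "max_angle",
    "rep_time_mean",
    "rep_time_variance",
    "depth_variance",
    "movement_stability",
)

N_ANGLE_FEATURES = len(ANGLE_FEATURE_NAMES)


class InsufficientRepetitionsError(ValueError):
    """Fewer than two full-flexion minima: repetition features undefined."""


@dataclass
class RepetitionProfile:
    """Detected full-flexion minima and the quantities derived from them."""

    minima_indices: np.ndarray  # frame indices, strictly increasing
    rep_times_frames: np.ndarray  # diffs of consecutive minima
    depths_deg: np.ndarray  # θ at each minimum

    def __post_init__(self) -> None:
        self.minima_indices = np.asarray(self.minima_indices, dtype=int)
        self.rep_times_frames = np.asarray(self.rep_times_frames, dtype=float)
        self.depths_deg = np.asarray(self.depths_deg, dtype=float)
        if np.any(np.diff(self.minima_indices) <= 0):
            raise ValueError("minima indices must be strictly increasing")
        if len(self.rep_times_frames) != len(self.minima_indices) - 1:
            raise ValueError("rep time count must be minima count - 1")


@dataclass
class AngleFeatures:
    """The nine kinematic features of one flexion trial (fixed order)."""

    variance: float
    std_dev: float
    min_angle: float
    range: float
    max_angle: float
    rep_time_mean: float
    rep_time_variance: float
    depth_variance: float
    movement_stability: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in ANGLE_FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in ANGLE_FEATURE_NAMES}


def detect_flexion_minima(
    wave: AngleWaveform,
    min_width_s: float = 0.25,
    max_width_s: float = 1.5,
    min_separation_s: float = 1.0,
    boundary_s: float = 0.5,
) -> np.ndarray:
    """Frame indices of full-flexion minima of a smoothed angle waveform.

    The waveform is negated and passed through CWT ridge-line peak detection
    with wavelet widths from ``min_width_s`` to ``max_width_s``, matched to
    the duration of the flexion dip (roughly half a repetition cycle across
    physiological cadences). Each candidate is snapped to the local
    minimum of θ within ±0.5 s; candidates within the first/last
    ``boundary_s`` are discarded as partial repetitions, and minima closer
    than ``min_separation_s`` are merged keeping the deeper one.
    """
    n = len(wave)
    fps = wave.fps
    if n < int(2 * fps):
        raise InsufficientRepetitionsError(
            f"waveform too short ({n} frames) for repetition detection"
        )
    widths = np.arange(max(1, int(min_width_s * fps)), int(max_width_s * fps) + 1)
    raw = find_peaks_cwt(-wave.theta, widths)
    raw = np.atleast_1d(np.asarray(raw, dtype=int))

    snap = max(1, int(0.5 * fps))
    snapped: set[int] = set()
    for p in raw:
        lo, hi = max(0, p - snap), min(n, p + snap + 1)
        snapped.add(int(lo + np.argmin(wave.theta[lo:hi])))

    border = int(boundary_s * fps)
    candidates = sorted(i for i in snapped if border <= i <= n - 1 - border)

    # enforce minimum separation, deepest minimum wins
    min_sep = int(min_separation_s * fps)
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: wave.theta[i]):
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    minima = np.array(sorted(kept), dtype=int)

    if len(minima) < 2:
        raise InsufficientRepetitionsError(
            f"only {len(minima)} full-flexion minima detected; need >= 2"
        )
    return minima


def repetition_times(minima_indices: np.ndarray, fps: float) -> np.ndarray:
    """Repetition times tr_i as frame counts between consecutive minima."""
    minima_indices = np.asarray(minima_indices)
    if len(minima_indices) < 2:
        raise InsufficientRepetitionsError("need >= 2 minima for repetition times")
    return np.diff(minima_indices).astype(float)


def movement_stability(wave: AngleWaveform) -> float:
    """Angle range of the second half of the trial minus that of the first.

    Positive values mean the participant increased their movement range as
    repetitions progressed. Halves split at floor(n/2).
    """
    n = len(wave)
    if n < 4:
        raise ValueError("waveform too short for movement stability (need >= 4 frames)")
    first, second = wave.theta[: n // 2], wave.theta[n // 2 :]
    return float((second.max() - second.min()) - (first.max() - first.min()))


def repetition_profile(
    wave: AngleWaveform, minima_indices: np.ndarray | None = None
) -> RepetitionProfile:
    """Build the repetition profile (minima, tr_i, depth_i) of a trial."""
    if minima_indices is None:
        minima_indices = detect_flexion_minima(wave)
    minima_indices = np.asarray(minima_indices, dtype=int)
    return RepetitionProfile(
        minima_indices=minima_indices,
        rep_times_frames=repetition_times(minima_indices, wave.fps),
        depths_deg=wave.theta[minima_indices],
    )


def extract_angle_features(
    wave: AngleWaveform, minima_indices: np.ndarray | None = None
) -> AngleFeatures:
    """Compute all nine kinematic features from a smoothed angle waveform.

    ``minima_indices`` may be supplied (e.g. generator ground truth);
    otherwise they are detected. A single repetition interval yields a
    repetition-time variance of 0 (one observation).
    """
    prof = repetition_profile(wave, minima_indices)
    theta = wave.theta
    tr = prof.rep_times_frames
    depths = prof.depths_deg
    return AngleFeatures(
        variance=float(np.var(theta, ddof=1)),
        std_dev=float(np.std(theta, ddof=1)),
        min_angle=float(theta.min()),
        range=float(theta.max() - theta.min()),
        max_angle=float(theta.max()),
        rep_time_mean=float(tr.mean()),
        rep_time_variance=float(np.var(tr, ddof=1)) if len(tr) > 1 else 0.0,
        depth_variance=float(np.var(depths, ddof=1)) if len(depths) > 1 else 0.0,
        movement_stability=movement_stability(wave),
    )
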