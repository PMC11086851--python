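"""Synthetic cohort generator for the flexion-classification pipeline.

Generates labelled participants — keypoint trajectories, mocap twins and
PROMs — with the statistical structure the analysis assumes, so every stage
of the pipeline can be exercised and validated without patient data.

Each participant performs 8–10 repetitions of forward spine flexion. A
repetition is a raised-cosine excursion of the flexion angle θ from the
standing angle θ_max down to a per-repetition depth and back, followed by a
short standing dwell; repetitions are preceded and followed by one second
of quiet standing. The two phenotypes differ primarily in kinematics:

* MI (movement impairment) — restricted flexion: shallow depths
  (θ_min ≈ 120°), slower repetitions (≈ 3.5 s), lower depth variability;
* MCI (motor control impairment) — unrestricted flexion: deep flexion
  (θ_min ≈ 85°), faster repetitions (≈ 2.5 s), higher depth variability.

PROMs are drawn from class-conditional truncated normals that overlap
almost completely between classes, except the STarT Back total, which
separates moderately (MI mean 3, MCI mean 6). This mirrors the qualitative
structure the classifier is meant to exploit: kinematics discriminate
strongly, questionnaires barely.

Keypoints are synthesised with the ankle at the origin, the hip fixed
vertically above it, and the neck on a trunk segment rotated by
φ(t) = 180° − θ(t), plus isotropic pixel noise. A mocap twin realises the
same latent θ(t) at 120 Hz in 3-D with C7, L4 and four pelvic markers,
with zero mediolateral motion and L4 co-located with the pelvic centroid
(above floor level, so the virtual-ankle construction is exercised).

Ground truth (per-repetition depths, periods, minima times) is retained in
a manifest for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .kinematics import AngleWaveform, KeypointTrajectory, MocapTrial
from .proms import PROM_RANGES, PROMS

LABELS = ("MI", "MCI")


@dataclass(frozen=True)
class ClassParams:
    """Latent kinematic distribution of one phenotype (angles deg, times s)."""

    theta_max_mean: float = 172.0
    theta_max_sd: float = 3.0
    theta_min_mean: float = 120.0
    theta_min_sd: float = 8.0
    period_mean_s: float = 3.5
    period_sd_s: float = 0.5
    period_jitter_sd_s: float = 0.2  # within-trial repetition-to-repetition
    depth_jitter_sd: float = 2.0  # within-trial depth variability (deg)


#: PROM name -> (MI mean, MCI mean, sd); ranges come from proms.PROM_RANGES
DEFAULT_PROMS_PARAMS: dict[str, tuple[float, float, float]] = {
    "vas": (55.0, 52.0, 15.0),
    "odi": (30.0, 28.0, 10.0),
    "tsk": (40.0, 39.0, 7.0),
    "pcs": (22.0, 21.0, 8.0),
    "pseq": (38.0, 40.0, 9.0),
    "csq": (35.0, 34.0, 9.0),
    "sbt": (3.0, 6.0, 1.5),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_mi: int = 41
    n_mci: int = 42
    fps: float = 30.0
    reps_min: int = 8
    reps_max: int = 10
    pixel_noise_sd: float = 1.0
    hip_height_px: float = 450.0
    trunk_length_px: float = 350.0
    hip_height_m: float = 1.0
    trunk_length_m: float = 0.55
    dwell_fraction: float = 0.1  # standing dwell between reps, fraction of period
    lead_in_s: float = 1.0
    lead_out_s: float = 1.0
    mocap_fps: float = 120.0
    seed: int = 0
    mi: ClassParams = ClassParams(
        theta_min_mean=120.0, period_mean_s=3.5, period_sd_s=0.5, depth_jitter_sd=2.0
    )
    mci: ClassParams = ClassParams(
        theta_min_mean=85.0, period_mean_s=2.5, period_sd_s=0.4,
        period_jitter_sd_s=0.2, depth_jitter_sd=4.0,
    )
    proms_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROMS_PARAMS)
    )

    def __post_init__(self) -> None:
        if self.n_mi < 1 or self.n_mci < 1:
            raise ValueError("need at least one participant per class")
        if not (1 <= self.reps_min <= self.reps_max):
            raise ValueError("invalid repetition range")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        for cp in (self.mi, self.mci):
            if cp.theta_min_mean >= cp.theta_max_mean:
                raise ValueError("theta_min_mean must be below theta_max_mean")

    def class_params(self, label: str) -> ClassParams:
        return self.mi if label == "MI" else self.mci


@dataclass
class GroundTruth:
    """Latent trial parameters retained for oracle tests."""

    theta_max: float
    depths: np.ndarray  # per-repetition minimum angle (deg)
    periods_s: np.ndarray  # per-repetition cycle duration
    dwells_s: np.ndarray
    lead_in_s: float
    lead_out_s: float

    @property
    def n_reps(self) -> int:
        return len(self.depths)

    @property
    def duration_s(self) -> float:
        return (
            self.lead_in_s
            + float(np.sum(self.periods_s) + np.sum(self.dwells_s))
            + self.lead_out_s
        )

    @property
    def minima_times_s(self) -> np.ndarray:
        """Times of the full-flexion minima (midpoint of each cycle)."""
        starts = self.lead_in_s + np.concatenate(
            ([0.0], np.cumsum(self.periods_s + self.dwells_s)[:-1])
        )
        return starts + self.periods_s / 2.0

    def minima_frames(self, fps: float) -> np.ndarray:
        return np.round(self.minima_times_s * fps).astype(int)

    def theta_at(self, t: np.ndarray) -> np.ndarray:
        """Latent flexion angle θ(t) in degrees at arbitrary times."""
        t = np.asarray(t, dtype=float)
        theta = np.full(t.shape, self.theta_max)
        start = self.lead_in_s
        for depth, period, dwell in zip(self.depths, self.periods_s, self.dwells_s):
            tau = t - start
            in_cycle = (tau >= 0) & (tau < period)
            theta[in_cycle] = self.theta_max - (self.theta_max - depth) * 0.5 * (
                1.0 - np.cos(2.0 * np.pi * tau[in_cycle] / period)
            )
            start += period + dwell
        return theta


@dataclass
class Participant:
    """One synthetic participant: trajectory, PROMs, label, latents."""

    participant_id: str
    label: str  # "MI" | "MCI"
    trajectory: KeypointTrajectory
    proms: PROMS
    ground_truth: GroundTruth

    @property
    def y(self) -> int:
        return 1 if self.label == "MI" else 0


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list[Participant]

    def labels(self) -> np.ndarray:
        return np.array([p.y for p in self.participants], dtype=int)


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_ground_truth(
    spec: CohortSpec, cp: ClassParams, rng: np.random.Generator
) -> GroundTruth:
    theta_max = _truncated_normal(cp.theta_max_mean, cp.theta_max_sd, 150.0, 179.5, rng)
    theta_min = _truncated_normal(
        cp.theta_min_mean, cp.theta_min_sd, 10.0, theta_max - 10.0, rng
    )
    n_reps = int(rng.integers(spec.reps_min, spec.reps_max + 1))
    depths = theta_min + rng.normal(0.0, cp.depth_jitter_sd, size=n_reps)
    depths = np.clip(depths, 5.0, theta_max - 5.0)
    periods = cp.period_mean_s + rng.normal(0.0, cp.period_sd_s)
    periods = periods + rng.normal(0.0, cp.period_jitter_sd_s, size=n_reps)
    periods = np.clip(periods, 1.2, 8.0)
    dwells = spec.dwell_fraction * periods
    return GroundTruth(
        theta_max=theta_max,
        depths=depths,
        periods_s=periods,
        dwells_s=dwells,
        lead_in_s=spec.lead_in_s,
        lead_out_s=spec.lead_out_s,
    )


def keypoints_from_theta(
    theta_deg: np.ndarray,
    fps: float,
    participant_id: str,
    hip_height: float = 450.0,
    trunk_length: float = 350.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> KeypointTrajectory:
    """Sagittal keypoints realising a given angle waveform.

    Ankle at the origin, hip fixed at ``hip_height`` above it, neck on a
    trunk segment rotated forward by φ = 180° − θ from vertical. Isotropic
    Gaussian pixel noise is added to every keypoint when ``noise_sd > 0``.
    """
    theta = np.asarray(theta_deg, dtype=float)
    n = theta.size
    phi = np.radians(180.0 - theta)
    ankle = np.zeros((n, 2))
    hip = np.column_stack([np.zeros(n), np.full(n, hip_height)])
    neck = hip + trunk_length * np.column_stack([np.sin(phi), np.cos(phi)])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        ankle = ankle + rng.normal(0.0, noise_sd, size=(n, 2))
        hip = hip + rng.normal(0.0, noise_sd, size=(n, 2))
        neck = neck + rng.normal(0.0, noise_sd, size=(n, 2))
    return KeypointTrajectory(
        participant_id=participant_id, fps=fps, ankle=ankle, hip=hip, neck=neck
    )


def _draw_proms(
    spec: CohortSpec, label: str, pid: str, rng: np.random.Generator
) -> PROMS:
    values = {}
    for name, (mi_mean, mci_mean, sd) in spec.proms_params.items():
        lo, hi = PROM_RANGES[name]
        mean = mi_mean if label == "MI" else mci_mean
        values[name] = _truncated_normal(mean, sd, lo, hi, rng)
    return PROMS(participant_id=pid, **values)


def generate_participant(
    spec: CohortSpec, label: str, rng: np.random.Generator, participant_id: str
) -> Participant:
    """Draw one labelled participant (trajectory + PROMs + ground truth)."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    gt = _draw_ground_truth(spec, spec.class_params(label), rng)
    n_frames = int(np.floor(gt.duration_s * spec.fps)) + 1
    t = np.arange(n_frames) / spec.fps
    traj = keypoints_from_theta(
        gt.theta_at(t),
        fps=spec.fps,
        participant_id=participant_id,
        hip_height=spec.hip_height_px,
        trunk_length=spec.trunk_length_px,
        noise_sd=spec.pixel_noise_sd,
        rng=rng,
    )
    proms = _draw_proms(spec, label, participant_id, rng)
    return Participant(participant_id, label, traj, proms, gt)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full labelled cohort, deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    participants = []
    order = ["MI"] * spec.n_mi + ["MCI"] * spec.n_mci
    for i, label in enumerate(order):
        pid = f"P{i + 1:03d}"
        participants.append(generate_participant(spec, label, rng, pid))
    return Cohort(spec=spec, participants=participants)


def generate_mocap_twin(
    gt: GroundTruth,
    spec: CohortSpec,
    participant_id: str = "mocap",
    marker_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MocapTrial:
    """120 Hz 3-D marker trial realising the same latent θ(t) as the video.

    C7 sits on the trunk segment, L4 coincides with the pelvic centroid
    (hip), and the four pelvic markers are rigid offsets around it whose
    mean is the hip. Mediolateral (z) motion is zero. Vertical axis is y
    with the floor at 0, so zeroing L4's vertical coordinate drops the
    virtual ankle to the floor directly beneath the hip.
    """
    n = int(np.floor(gt.duration_s * spec.mocap_fps)) + 1
    t = np.arange(n) / spec.mocap_fps
    phi = np.radians(180.0 - gt.theta_at(t))
    hip = np.column_stack([np.zeros(n), np.full(n, spec.hip_height_m), np.zeros(n)])
    trunk = spec.trunk_length_m * np.column_stack(
        [np.sin(phi), np.cos(phi), np.zeros(n)]
    )
    offsets = {
        "LASIS": np.array([0.09, 0.0, 0.08]),
        "RASIS": np.array([0.09, 0.0, -0.08]),
        "LPSIS": np.array([-0.09, 0.0, 0.08]),
        "RPSIS": np.array([-0.09, 0.0, -0.08]),
    }
    markers = {"C7": hip + trunk, "L4": hip.copy()}
    for name, off in offsets.items():
        markers[name] = hip + off
    if marker_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, marker_noise_sd, size=(n, 3)
            )
            # keep the floor constraint of the capture volume
            markers[name][:, 1] = np.maximum(markers[name][:, 1], 0.0)
    return MocapTrial(
        participant_id=participant_id,
        markers=markers,
        fps=spec.mocap_fps,
        vertical_axis=1,
        units="m",
    )


def cohort_manifest(cohort: Cohort) -> dict:
    """JSON-serialisable record of every latent parameter of the cohort."""
    spec = cohort.spec
    return {
        "seed": spec.seed,
        "n_mi": spec.n_mi,
        "n_mci": spec.n_mci,
        "fps": spec.fps,
        "pixel_noise_sd": spec.pixel_noise_sd,
        "participants": [
            {
                "participant_id": p.participant_id,
                "label": p.label,
                "theta_max": p.ground_truth.theta_max,
                "depths": p.ground_truth.depths.tolist(),
                "periods_s": p.ground_truth.periods_s.tolist(),
                "dwells_s": p.ground_truth.dwells_s.tolist(),
                "minima_frames": p.ground_truth.minima_frames(spec.fps).tolist(),
                "proms": p.proms.as_dict(),
            }
            for p in cohort.participants
        ],
    }
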