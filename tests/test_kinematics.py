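"""Spine-flexion angle computation, smoothing, mocap mapping and MSE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spineflex.kinematics import (
    AngleWaveform,
    DegenerateGeometryError,
    FpsMismatchError,
    KeypointTrajectory,
    MocapTrial,
    angle_waveform,
    mocap_spine_angle,
    resample_waveform,
    smooth_waveform,
    spine_flexion_angle,
    waveform_mse,
)
from spineflex.synthetic import CohortSpec, generate_mocap_twin, keypoints_from_theta


def dot_product_angle(ankle, hip, neck):
    """Independent oracle: angle at the hip from the dot product."""
    u = np.asarray(ankle, float) - np.asarray(hip, float)
    v = np.asarray(neck, float) - np.asarray(hip, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


class TestSpineFlexionAngle:
    @pytest.mark.parametrize(
        "ankle, hip, neck, expected",
        [
            ((0, 0), (0, 1), (0, 2), 180.0),  # collinear, standing
            ((0, 0), (0, 1), (1, 1), 90.0),  # right angle at the hip
            ((0, 0), (1, 0), (0.5, 0.8660254), 60.0),  # equilateral triangle
        ],
    )
    def test_known_geometries(self, ankle, hip, neck, expected):
        assert spine_flexion_angle(ankle, hip, neck) == pytest.approx(expected, abs=1e-6)

    def test_matches_dot_product_oracle_on_random_triangles(self, rng):
        for _ in range(1000):
            pts = rng.uniform(-100, 100, size=(3, 2))
            if min(np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[2] - pts[1])) < 1e-6:
                continue
            ankle, hip, neck = pts
            assert spine_flexion_angle(ankle, hip, neck) == pytest.approx(
                dot_product_angle(ankle, hip, neck), abs=1e-9
            )

    def test_works_in_three_dimensions(self, rng):
        pts = rng.uniform(-1, 1, size=(3, 3))
        ankle, hip, neck = pts
        assert spine_flexion_angle(ankle, hip, neck) == pytest.approx(
            dot_product_angle(ankle, hip, neck), abs=1e-9
        )

    @pytest.mark.parametrize(
        "ankle, hip, neck, pair",
        [
            ((0, 0), (1, 1), (1, 1), "hip and neck"),
            ((1, 1), (1, 1), (0, 0), "ankle and hip"),
        ],
    )
    def test_degenerate_geometry_names_offending_pair(self, ankle, hip, neck, pair):
        with pytest.raises(DegenerateGeometryError, match=pair):
            spine_flexion_angle(ankle, hip, neck)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 100),
        rot=st.floats(0, 2 * np.pi),
        tx=st.floats(-500, 500),
        ty=st.floats(-500, 500),
        reflect=st.booleans(),
        seed=st.integers(0, 10_000),
    )
    def test_similarity_transform_invariance(self, scale, rot, tx, ty, reflect, seed):
        """θ depends only on shape: scaling/rotation/translation/reflection."""
        pts = np.random.default_rng(seed).uniform(-10, 10, size=(3, 2))
        if min(
            np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[2] - pts[1])
        ) < 1e-3:
            return
        theta0 = spine_flexion_angle(*pts)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        if reflect:
            R = R @ np.diag([1.0, -1.0])
        moved = scale * pts @ R.T + np.array([tx, ty])
        assert spine_flexion_angle(*moved) == pytest.approx(theta0, abs=1e-9)


class TestAngleWaveform:
    def test_constant_upright_geometry_gives_180(self):
        n = 100
        traj = KeypointTrajectory(
            "p", 30.0,
            ankle=np.zeros((n, 2)),
            hip=np.tile([0.0, 1.0], (n, 1)),
            neck=np.tile([0.0, 2.0], (n, 1)),
        )
        wave = angle_waveform(traj)
        assert wave.source == "pose" and not wave.smoothed
        np.testing.assert_allclose(wave.theta, 180.0)

    def test_round_trip_recovers_generator_theta(self):
        t = np.arange(300) / 30.0
        theta = 150.0 + 25.0 * np.cos(2 * np.pi * t / 3.0)
        traj = keypoints_from_theta(theta, 30.0, "p")
        np.testing.assert_allclose(angle_waveform(traj).theta, theta, atol=1e-6)

    def test_empty_trajectory_rejected(self):
        traj = KeypointTrajectory(
            "p", 30.0, np.empty((0, 2)), np.empty((0, 2)), np.empty((0, 2))
        )
        with pytest.raises(ValueError, match="empty"):
            angle_waveform(traj)

    def test_degenerate_frame_reports_index(self):
        hip = np.tile([0.0, 1.0], (5, 1))
        neck = np.tile([0.0, 2.0], (5, 1))
        neck[3] = hip[3]  # collapse hip/neck at frame 3
        traj = KeypointTrajectory("p", 30.0, np.zeros((5, 2)), hip, neck)
        with pytest.raises(DegenerateGeometryError, match="frame 3"):
            angle_waveform(traj)


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        wave = AngleWaveform(np.full(90, 150.0), 30.0)
        out = smooth_waveform(wave)
        assert out.smoothed and len(out) == 90
        np.testing.assert_allclose(out.theta, 150.0)

    def test_linear_ramp_interior_shifts_at_most_half_step(self):
        # even window: centered mean of a line moves by half the frame step
        theta = np.linspace(100, 160, 120)
        step = theta[1] - theta[0]
        out = smooth_waveform(AngleWaveform(theta, 30.0), 30)
        assert np.max(np.abs(out.theta[20:-20] - theta[20:-20])) <= step / 2 + 1e-9

    def test_impulse_spreads_to_one_over_window(self):
        # direct convolution oracle: interior values of a unit impulse
        theta = np.full(200, 100.0)
        theta[100] += 30.0
        out = smooth_waveform(AngleWaveform(theta, 30.0), 30)
        oracle = 100.0 + np.convolve(theta - 100.0, np.ones(30) / 30.0, mode="same")
        np.testing.assert_allclose(out.theta[40:-40], oracle[40:-40], atol=1e-9)

    def test_output_range_never_exceeds_input_range(self, rng):
        theta = rng.uniform(60, 170, size=200)
        out = smooth_waveform(AngleWaveform(theta, 30.0), 30)
        assert out.theta.min() >= theta.min() - 1e-12
        assert out.theta.max() <= theta.max() + 1e-12

    def test_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_waveform(AngleWaveform(np.full(10, 150.0), 30.0), 30)


class TestMocapAngle:
    def test_collinear_construction_gives_180(self):
        n = 10
        hip = np.tile([0.0, 1.0, 0.0], (n, 1))
        markers = {
            "C7": np.tile([0.0, 1.5, 0.0], (n, 1)),
            "L4": hip.copy(),
            "LASIS": hip + [0.1, 0, 0.1],
            "RASIS": hip + [0.1, 0, -0.1],
            "LPSIS": hip + [-0.1, 0, 0.1],
            "RPSIS": hip + [-0.1, 0, -0.1],
        }
        trial = MocapTrial("p", markers)
        wave = mocap_spine_angle(trial)
        assert wave.source == "mocap"
        np.testing.assert_allclose(wave.theta, 180.0, atol=1e-9)

    def test_twin_recovers_latent_theta(self):
        spec = CohortSpec(seed=0)
        from spineflex.synthetic import GroundTruth

        gt = GroundTruth(
            theta_max=172.0, depths=np.array([100.0, 95.0]),
            periods_s=np.array([3.0, 3.0]), dwells_s=np.array([0.3, 0.3]),
            lead_in_s=1.0, lead_out_s=1.0,
        )
        trial = generate_mocap_twin(gt, spec)
        wave = mocap_spine_angle(trial)
        t = np.arange(trial.n_frames) / trial.fps
        np.testing.assert_allclose(wave.theta, gt.theta_at(t), atol=1e-6)

    def test_virtual_ankle_when_l4_already_on_floor(self):
        n = 5
        markers = {
            "C7": np.tile([0.2, 1.5, 0.0], (n, 1)),
            "L4": np.tile([0.0, 0.0, 0.0], (n, 1)),  # vertical already zero
            "LASIS": np.tile([0.1, 1.0, 0.1], (n, 1)),
            "RASIS": np.tile([0.1, 1.0, -0.1], (n, 1)),
            "LPSIS": np.tile([-0.1, 1.0, 0.1], (n, 1)),
            "RPSIS": np.tile([-0.1, 1.0, -0.1], (n, 1)),
        }
        trial = MocapTrial("p", markers)
        # vA coincides with L4; angle equals direct computation with L4 as ankle
        wave = mocap_spine_angle(trial)
        expected = spine_flexion_angle(
            markers["L4"][0], [0.0, 1.0, 0.0], markers["C7"][0]
        )
        np.testing.assert_allclose(wave.theta, expected, atol=1e-9)

    def test_missing_marker_rejected(self):
        markers = {"C7": np.zeros((5, 3))}
        with pytest.raises(ValueError, match="missing"):
            MocapTrial("p", markers)

    def test_marker_gap_rejected_without_fill(self):
        n = 5
        markers = {
            m: np.tile([0.1, 1.0, 0.0], (n, 1))
            for m in ("C7", "L4", "LASIS", "RASIS", "LPSIS", "RPSIS")
        }
        markers["L4"][2, 1] = np.nan
        with pytest.raises(ValueError, match="gaps"):
            MocapTrial("p", markers)


class TestResampleAndMse:
    def test_downsample_constant(self):
        wave = AngleWaveform(np.full(121, 150.0), 120.0)
        out = resample_waveform(wave, 30.0)
        assert len(out) == 31 and out.fps == 30.0
        np.testing.assert_allclose(out.theta, 150.0)

    def test_downsample_ramp_keeps_values_at_retained_times(self):
        theta = np.linspace(100, 160, 121)  # 1 s at 120 Hz
        out = resample_waveform(AngleWaveform(theta, 120.0), 30.0)
        np.testing.assert_allclose(out.theta, theta[::4], atol=1e-12)

    def test_downsample_sinusoid_matches_analytic(self):
        t120 = np.arange(0, 8, 1 / 120)
        f = lambda t: 140 + 30 * np.sin(2 * np.pi * t / 2.5)
        out = resample_waveform(AngleWaveform(f(t120), 120.0), 30.0)
        t30 = np.arange(len(out)) / 30.0
        assert np.max(np.abs(out.theta - f(t30))) < 0.1

    def test_mse_identical_zero(self):
        w = AngleWaveform(np.linspace(100, 160, 50), 30.0)
        assert waveform_mse(w, w) == 0.0

    def test_mse_constant_offset_is_offset_squared(self):
        a = AngleWaveform(np.full(40, 150.0), 30.0)
        b = AngleWaveform(np.full(40, 152.0), 30.0)
        assert waveform_mse(a, b) == pytest.approx(4.0)

    def test_mse_matches_direct_computation(self, rng):
        x = rng.uniform(100, 170, 10)
        y = rng.uniform(100, 170, 10)
        expected = np.mean((x - y) ** 2)
        got = waveform_mse(AngleWaveform(x, 30.0), AngleWaveform(y, 30.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_mse_fps_mismatch_instructs_resampling(self):
        a = AngleWaveform(np.full(40, 150.0), 30.0)
        b = AngleWaveform(np.full(40, 150.0), 120.0)
        with pytest.raises(FpsMismatchError, match="resample"):
            waveform_mse(a, b)

    def test_mse_truncates_small_length_mismatch_only(self):
        a = AngleWaveform(np.full(40, 150.0), 30.0)
        b = AngleWaveform(np.full(42, 150.0), 30.0)
        assert waveform_mse(a, b) == 0.0
        c = AngleWaveform(np.full(50, 150.0), 30.0)
        with pytest.raises(ValueError, match="differ"):
            waveform_mse(a, c)
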