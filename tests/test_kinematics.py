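"""Pose filtering, anatomical frames, Euler decomposition, speed, and
time normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from bvrkin.kinematics import (
    AnatomicalFrame,
    GimbalLockError,
    build_anatomical_frame,
    decompose_xyz,
    filter_pose_sequence,
    kinematics_table,
    recompose_xyz,
    relative_pose,
    tibial_speed,
    time_normalize,
)
from bvrkin.transforms import RigidTransform
from oracles import butterworth_gain

FS = 250.0


def _sine_translation_poses(freq, n, amplitude=1.0):
    t = np.arange(n) / FS
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return [RigidTransform(np.eye(3), [xi, 0.0, 0.0]) for xi in x], x


def _demodulated_amplitude(x, freq):
    """Amplitude at freq via quadrature demodulation over the central half."""
    n = len(x)
    sl = slice(n // 4, n // 4 + n // 2)
    t = np.arange(n)[sl] / FS
    xs = x[sl]
    c = np.mean(xs * np.cos(2 * np.pi * freq * t))
    s = np.mean(xs * np.sin(2 * np.pi * freq * t))
    return 2.0 * np.hypot(c, s)


class TestFilterPoseSequence:
    def test_constant_pose_passes_unchanged(self):
        pose = RigidTransform.from_rotvec([0.2, -0.1, 0.3], [10.0, -5.0, 2.0])
        out = filter_pose_sequence([pose] * 50, FS)
        for t in out:
            assert t.is_close(pose, atol=1e-9)

    def test_stopband_sinusoid_attenuated_to_analytic_level(self):
        poses, _ = _sine_translation_poses(50.0, 2000)
        out = filter_pose_sequence(poses, FS)
        amp = _demodulated_amplitude(np.array([t.translation[0] for t in out]), 50.0)
        assert amp < 0.02                      # 50 Hz is far above the 10 Hz cutoff
        expected = butterworth_gain(50.0, 10.0)
        assert amp == pytest.approx(expected, rel=0.15)

    def test_passband_sinusoid_preserved_to_analytic_level(self):
        poses, _ = _sine_translation_poses(1.0, 2000)
        out = filter_pose_sequence(poses, FS)
        amp = _demodulated_amplitude(np.array([t.translation[0] for t in out]), 1.0)
        assert amp > 0.99                      # 1 Hz sits well inside the passband
        expected = butterworth_gain(1.0, 10.0)
        assert amp == pytest.approx(expected, abs=1e-3)

    def test_rotation_components_filtered_like_translations(self):
        t = np.arange(2000) / FS
        angles = 5.0 * np.sin(2 * np.pi * 50.0 * t)   # degrees about x
        poses = [
            RigidTransform(Rotation.from_euler("x", a, degrees=True).as_matrix(), [0, 0, 0])
            for a in angles
        ]
        out = filter_pose_sequence(poses, FS)
        out_angles = np.degrees(
            [np.sign(t.rotation[2, 1]) * t.rotation_angle() for t in out]
        )
        amp = _demodulated_amplitude(np.array(out_angles), 50.0)
        assert amp < 0.02 * 5.0

    def test_filtering_does_not_bias_a_constant(self):
        pose = RigidTransform(np.eye(3), [3.0, 0.0, 0.0])
        out = filter_pose_sequence([pose] * 100, FS)
        diffs = np.array([t.translation[0] - 3.0 for t in out])
        assert abs(diffs.mean()) < 1e-12

    def test_single_pass_variant_runs(self):
        poses, _ = _sine_translation_poses(50.0, 500)
        out = filter_pose_sequence(poses, FS, zero_phase=False)
        amp = np.abs([t.translation[0] for t in out][100:]).max()
        assert amp < 0.1

    def test_too_short_sequence_rejected(self):
        pose = RigidTransform.identity()
        with pytest.raises(ValueError, match="at least 7 frames"):
            filter_pose_sequence([pose] * 6, FS)


IDENTITY_ACS = AnatomicalFrame("femur", RigidTransform.identity())
IDENTITY_ACS_T = AnatomicalFrame("tibia", RigidTransform.identity())


class TestRelativePose:
    def test_identical_poses_and_frames_give_identity(self, rng):
        pose = RigidTransform.from_rotvec(rng.normal(0, 0.3, 3), rng.normal(0, 30, 3))
        acs = AnatomicalFrame("femur", RigidTransform.from_rotvec([0.1, 0, 0], [1, 2, 3]))
        acs_t = AnatomicalFrame("tibia", acs.transform)
        rel = relative_pose(pose, pose, acs, acs_t)
        assert rel.is_close(RigidTransform.identity(), atol=1e-12)

    def test_frozen_specimen_constant_relative_pose(self, geometry, specimen, quiet_trial_cfg):
        from bvrkin.scene import simulate_trial

        trial = simulate_trial(specimen, geometry, quiet_trial_cfg)
        acs_f = build_anatomical_frame(specimen.femur)
        acs_t = build_anatomical_frame(specimen.tibia)
        rels = [
            relative_pose(f, t, acs_f, acs_t).as_matrix()
            for f, t in zip(trial.truth["femur"], trial.truth["tibia"])
        ]
        spread = np.ptp(np.stack(rels), axis=0).max()
        assert spread < 1e-12

    def test_hand_computed_rx30_offset(self):
        # femur at identity, tibia offset by Rx(30°) + (1,2,3); identity ACS:
        # the relative pose is exactly the tibia pose
        tibia = recompose_xyz(30.0, 0.0, 0.0, 1.0, 2.0, 3.0)
        rel = relative_pose(RigidTransform.identity(), tibia, IDENTITY_ACS, IDENTITY_ACS_T)
        assert rel.is_close(tibia, atol=1e-12)
        # moving both bones by a common lab transform leaves it unchanged
        common = RigidTransform.from_rotvec([0.3, -0.2, 0.1], [5, 6, 7])
        rel2 = relative_pose(common, common @ tibia, IDENTITY_ACS, IDENTITY_ACS_T)
        assert rel2.is_close(tibia, atol=1e-9)
        np.testing.assert_allclose(
            decompose_xyz(rel), [30.0, 0.0, 0.0, 1.0, 2.0, 3.0], atol=1e-12
        )


class TestDecomposeXYZ:
    def test_identity_gives_zeros(self):
        np.testing.assert_allclose(decompose_xyz(RigidTransform.identity()), 0.0, atol=1e-12)

    def test_pure_flexion(self):
        np.testing.assert_allclose(
            decompose_xyz(recompose_xyz(30.0, 0, 0)), [30, 0, 0, 0, 0, 0], atol=1e-12
        )

    def test_roundtrip_over_random_poses(self, rng):
        mats = Rotation.random(1000, rng=np.random.default_rng(55)).as_matrix()
        for m in mats:
            pose = RigidTransform(m, rng.uniform(-20, 20, 3))
            try:
                fe, aa, ie, ml, ap, is_ = decompose_xyz(pose)
            except GimbalLockError:
                continue
            back = recompose_xyz(fe, aa, ie, ml, ap, is_)
            assert np.abs(back.as_matrix() - pose.as_matrix()).max() < 1e-9

    def test_matches_scipy_euler_convention(self, rng):
        for m in Rotation.random(50, rng=np.random.default_rng(56)).as_matrix():
            fe, aa, ie, *_ = decompose_xyz(RigidTransform(m, np.zeros(3)))
            sp = Rotation.from_matrix(m).as_euler("XYZ", degrees=True)
            np.testing.assert_allclose([fe, aa, ie], sp, atol=1e-9)

    def test_gimbal_lock_raises(self):
        with pytest.raises(GimbalLockError):
            decompose_xyz(recompose_xyz(10.0, 90.0, 20.0))


class TestTibialSpeed:
    def test_stationary_trial_zero_speed(self):
        pose = RigidTransform.identity()
        speed, mean = tibial_speed([pose] * 20, FS)
        np.testing.assert_allclose(speed, 0.0)
        assert mean == 0.0

    @pytest.mark.parametrize("v", [1.8, 0.9])
    def test_constant_velocity_recovered_exactly(self, v):
        t = np.arange(50) / FS
        poses = [RigidTransform(np.eye(3), [0, 0, -v * 1000.0 * ti]) for ti in t]
        speed, mean = tibial_speed(poses, FS)
        np.testing.assert_allclose(speed, v, atol=1e-9)
        assert mean == pytest.approx(v, abs=1e-9)


class TestTimeNormalize:
    def _table(self, n):
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "FE": np.linspace(10, 20, n),
                "AA": np.zeros(n),
                "motion": "hop",
            }
        )

    @pytest.mark.parametrize("n_out", [75, 10])
    def test_output_row_counts(self, n_out):
        out = time_normalize(self._table(33), n_out)
        assert len(out) == n_out

    def test_linear_ramp_interpolates_exactly(self):
        out = time_normalize(self._table(40), 75)
        np.testing.assert_allclose(out["FE"], np.linspace(10, 20, 75), atol=1e-12)

    def test_endpoints_preserved(self):
        tab = self._table(13)
        out = time_normalize(tab, 10)
        assert out["FE"].iloc[0] == tab["FE"].iloc[0]
        assert out["FE"].iloc[-1] == tab["FE"].iloc[-1]
        assert (out["motion"] == "hop").all()


class TestAnatomicalFrame:
    def test_canonical_landmarks_give_near_identity(self):
        lms = {
            "medial_epicondyle": [-40.0, 0, 0],
            "lateral_epicondyle": [40.0, 0, 0],
            "proximal_shaft": [0.0, 0, 180.0],
        }
        acs = build_anatomical_frame(name="femur", landmarks=lms)
        assert acs.transform.is_close(RigidTransform.identity(), atol=1e-12)

    def test_mirrored_landmarks_stay_right_handed(self):
        lms = {
            "medial_epicondyle": [40.0, 0, 0],    # left knee: medial on +X
            "lateral_epicondyle": [-40.0, 0, 0],
            "proximal_shaft": [3.0, 5.0, 180.0],
        }
        acs = build_anatomical_frame(name="femur", landmarks=lms)
        assert np.linalg.det(acs.transform.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_missing_landmark_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_anatomical_frame(name="tibia", landmarks={"medial_plateau": [0, 0, 0]})

    def test_frozen_pose_flexion_in_hop_range(self):
        from bvrkin.scene import generate_specimen

        for seed in (1, 2, 3):
            s = generate_specimen(seed)
            acs_f = build_anatomical_frame(s.femur)
            acs_t = build_anatomical_frame(s.tibia)
            rel = acs_f.transform @ s.frozen_relative_pose @ acs_t.transform.inverse()
            fe = decompose_xyz(rel)[0]
            assert 20.0 <= fe <= 55.0

    def test_difference_magnitudes_invariant_to_acs_axis_convention(self, rng):
        # rotating the anatomical axis convention (same origin) must not
        # change the size of a tracking discrepancy, only how it splits
        # across the six DOFs
        from bvrkin.agreement import per_bone_differences
        from bvrkin.scene import generate_specimen

        s = generate_specimen(seed=42)
        acs1 = build_anatomical_frame(s.femur)
        spin = RigidTransform.from_rotvec([0.0, 0.0, np.radians(40.0)], [0, 0, 0])
        acs2 = AnatomicalFrame("femur", spin @ acs1.transform)
        marker = [RigidTransform.from_rotvec(rng.normal(0, 0.2, 3), rng.normal(0, 20, 3))
                  for _ in range(10)]
        model = [
            t @ RigidTransform.from_rotvec(rng.normal(0, 0.01, 3), rng.normal(0, 0.5, 3))
            for t in marker
        ]
        mags = []
        for acs in (acs1, acs2):
            d = per_bone_differences(marker, model, acs)
            wide = d.pivot(index="frame", columns="dof", values="diff")
            rot = np.stack(
                [Rotation.from_euler("XYZ", wide[["FE", "AA", "IE"]].to_numpy()[i], degrees=True).magnitude()
                 for i in range(len(wide))]
            )
            trans = np.linalg.norm(wide[["ML", "AP", "IS"]].to_numpy(), axis=1)
            mags.append((rot, trans))
        np.testing.assert_allclose(mags[0][0], mags[1][0], atol=1e-9)
        np.testing.assert_allclose(mags[0][1], mags[1][1], atol=1e-9)


class TestKinematicsTable:
    def test_columns_and_metadata(self, rng):
        femur = [RigidTransform.identity()] * 5
        tibia = [recompose_xyz(25.0, 1.0, -2.0, 0.5, -1.0, -40.0)] * 5
        tab = kinematics_table(femur, tibia, IDENTITY_ACS, IDENTITY_ACS_T, FS,
                               method="marker", motion="hop")
        assert list(tab.columns[:8]) == ["frame", "FE", "AA", "IE", "ML", "AP", "IS", "speed"]
        np.testing.assert_allclose(tab["FE"], 25.0, atol=1e-9)
        assert (tab["method"] == "marker").all()
        np.testing.assert_allclose(tab["speed"], 0.0, atol=1e-12)
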