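"""Accuracy (MAD), Bland–Altman bias/precision, LoA confidence intervals,
and the stratified agreement analyses."""

import numpy as np
import pandas as pd
import pytest

from bvrkin.agreement import (
    accuracy_mad,
    bland_altman,
    common_frame_run,
    compute_differences,
    frame_differences,
    loa_confidence_interval,
    per_bone_differences,
    stratified_report,
    summarize_differences,
)
from bvrkin.kinematics import DOF_COLUMNS, build_anatomical_frame, decompose_xyz
from bvrkin.markers import track_trial
from bvrkin.scene import TrialConfig, emulate_trial_model, simulate_trial
from bvrkin.transforms import RigidTransform


def _table(n=10, **overrides):
    base = {c: np.zeros(n) for c in DOF_COLUMNS}
    base.update(overrides)
    df = pd.DataFrame(base)
    df.insert(0, "frame", np.arange(n))
    return df


class TestFrameDifferences:
    def test_equal_tables_give_zero(self):
        d = frame_differences(_table(), _table())
        assert (d["diff"] == 0).all()

    def test_single_dof_offset_isolated(self):
        d = frame_differences(_table(FE=np.full(10, 0.5)), _table())
        assert (d.loc[d.dof == "FE", "diff"] == 0.5).all()
        assert (d.loc[d.dof != "FE", "diff"] == 0).all()
        assert (d.loc[d.dof == "FE", "pair_mean"] == 0.25).all()

    def test_matches_elementwise_subtraction(self, rng):
        a = _table(**{c: rng.normal(size=10) for c in DOF_COLUMNS})
        b = _table(**{c: rng.normal(size=10) for c in DOF_COLUMNS})
        d = frame_differences(a, b)
        for dof in DOF_COLUMNS:
            np.testing.assert_allclose(
                d.loc[d.dof == dof, "diff"].to_numpy(),
                a[dof].to_numpy() - b[dof].to_numpy(),
            )

    def test_frame_mismatch_lists_missing(self):
        b = _table()
        b["frame"] += 5
        with pytest.raises(ValueError, match="frame mismatch"):
            frame_differences(_table(), b)


class TestAccuracyMad:
    def test_hand_example(self):
        mad, sd = accuracy_mad([0.3, -0.3, 0.3])
        assert mad == pytest.approx(0.3)
        assert sd == pytest.approx(0.0)

    def test_all_zero(self):
        assert accuracy_mad(np.zeros(5)) == (0.0, 0.0)

    def test_half_normal_expectation_at_large_n(self):
        rng = np.random.default_rng(101)
        sigma = 0.7
        d = rng.normal(0, sigma, 1_000_000)
        mad, _ = accuracy_mad(d)
        assert mad == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.01)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            accuracy_mad([0.1])


class TestBlandAltman:
    def test_constant_differences(self):
        ba = bland_altman(np.full(10, 2.5))
        assert ba["bias"] == pytest.approx(2.5)
        assert ba["loa"] == 0.0
        assert ba["outlier_frac"] == 0.0

    def test_two_point_hand_arithmetic(self):
        ba = bland_altman([0.0, 2.0])
        assert ba["bias"] == pytest.approx(1.0)
        assert ba["sd"] == pytest.approx(np.sqrt(2.0))
        assert ba["loa"] == pytest.approx(1.96 * np.sqrt(2.0))

    def test_standard_normal_loa_and_outlier_rate(self):
        rng = np.random.default_rng(7)
        ba = bland_altman(rng.standard_normal(100_000))
        assert ba["loa"] == pytest.approx(1.96, abs=0.02)
        assert ba["outlier_frac"] == pytest.approx(0.05, abs=0.003)


class TestLoaConfidenceInterval:
    def test_pooled_rotational_bound(self):
        # SD back-computed from a pooled IE LoA of 1.19 at n = 1974 frames
        sd = 1.19 / 1.96
        ci = loa_confidence_interval(sd, 1974)
        assert ci == pytest.approx(1.96 * np.sqrt(3 / 1974) * sd)
        assert ci < 0.1

    def test_pooled_translational_bound(self):
        sd = 0.95 / 1.96    # pooled AP LoA 0.95 mm
        assert loa_confidence_interval(sd, 1974) < 0.08

    def test_zero_sd(self):
        assert loa_confidence_interval(0.0, 100) == 0.0

    def test_scaling_with_n(self):
        assert loa_confidence_interval(1.0, 400) == pytest.approx(
            loa_confidence_interval(1.0, 100) / 2.0
        )


class TestPerBoneDifferences:
    def test_identical_sequences_give_zero(self, specimen):
        acs = build_anatomical_frame(specimen.femur)
        seq = [RigidTransform.identity()] * 5
        d = per_bone_differences(seq, seq, acs)
        np.testing.assert_allclose(d["diff"], 0.0, atol=1e-12)

    def test_offset_along_bone_x_appears_in_ml(self, specimen, rng):
        acs = build_anatomical_frame(specimen.femur)
        marker = [RigidTransform.from_rotvec(rng.normal(0, 0.2, 3), rng.normal(0, 20, 3))
                  for _ in range(4)]
        # shift the model pose by +0.5 mm along the bone's anatomical X
        shift_ct = RigidTransform(
            np.eye(3), acs.transform.rotation.T @ np.array([0.5, 0.0, 0.0])
        )
        model = [t @ shift_ct for t in marker]
        d = per_bone_differences(marker, model, acs)
        assert d.loc[d.dof == "ML", "diff"].to_numpy() == pytest.approx(0.5, abs=1e-9)
        for dof in ("FE", "AA", "IE", "AP", "IS"):
            np.testing.assert_allclose(d.loc[d.dof == dof, "diff"], 0.0, atol=1e-9)

    def test_matches_matrix_algebra_oracle(self, specimen, rng):
        acs = build_anatomical_frame(specimen.tibia)
        marker = [RigidTransform.from_rotvec(rng.normal(0, 0.2, 3), rng.normal(0, 20, 3))
                  for _ in range(6)]
        model = [
            t @ RigidTransform.from_rotvec(rng.normal(0, 0.005, 3), rng.normal(0, 0.3, 3))
            for t in marker
        ]
        d = per_bone_differences(marker, model, acs)
        a = acs.transform.as_matrix()
        for k, (tm, to) in enumerate(zip(marker, model)):
            delta = a @ np.linalg.inv(tm.as_matrix()) @ to.as_matrix() @ np.linalg.inv(a)
            expected = decompose_xyz(RigidTransform.from_matrix(delta))
            got = d[d.frame == k].set_index("dof")["diff"]
            np.testing.assert_allclose(
                [got[c] for c in DOF_COLUMNS], expected, atol=1e-9
            )


def _make_trials(specimen, geometry, n_hop=2, n_drop=2, seed0=500, **noise):
    cfgs = []
    for j in range(n_hop):
        cfgs.append(TrialConfig(motion="hop", mean_speed_mps=0.9, speed_sd_mps=0.2,
                                duration_s=0.1, seed=seed0 + j, **noise))
    for j in range(n_drop):
        cfgs.append(TrialConfig(motion="drop", mean_speed_mps=1.8, speed_sd_mps=0.3,
                                duration_s=0.04, seed=seed0 + 50 + j, **noise))
    trials = []
    for i, cfg in enumerate(cfgs):
        t = simulate_trial(specimen, geometry, cfg, f"t{i}_{cfg.motion}")
        emulate_trial_model(t, specimen, cfg, geometry.frame_rate_hz)
        track_trial(t, {"femur": specimen.femur, "tibia": specimen.tibia}, geometry)
        trials.append(t)
    return trials


class TestStratifiedReport:
    def test_degenerate_stratification_equals_pooled(self, specimen, geometry):
        # one specimen, one motion: every joint-level stratum repeats pooled
        trials = _make_trials(specimen, geometry, n_hop=2, n_drop=0)
        report = stratified_report(trials, {specimen.specimen_id: specimen})
        pooled = report[report.analysis == "pooled"].set_index("dof")
        for analysis in ("specimen", "motion"):
            sub = report[report.analysis == analysis]
            assert sub["stratum"].nunique() == 1
            for _, row in sub.iterrows():
                assert row["mad"] == pytest.approx(pooled.loc[row.dof, "mad"])
                assert row["loa"] == pytest.approx(pooled.loc[row.dof, "loa"])

    def test_count_conservation_across_stratifications(self, specimen, geometry):
        trials = _make_trials(specimen, geometry)
        report = stratified_report(trials, {specimen.specimen_id: specimen})
        pooled_n = report.loc[report.analysis == "pooled", "n"].sum()
        for analysis in ("specimen", "motion"):
            assert report.loc[report.analysis == analysis, "n"].sum() == pooled_n
        # per-bone analysis covers both bones on the same frames
        assert report.loc[report.analysis == "bone", "n"].sum() == 2 * pooled_n

    def test_equal_noise_motions_differ_only_by_sampling(self, specimen, geometry):
        # drop and hop trials share the noise model, so the observed
        # hop-drop MAD gap must sit inside the trial-permutation null
        trials = _make_trials(specimen, geometry, n_hop=4, n_drop=4)
        joint, _ = compute_differences(trials, {specimen.specimen_id: specimen})
        per_trial = (
            joint[joint.dof == "FE"]
            .groupby("trial")
            .agg(mad=("diff", lambda d: np.abs(d).mean()), motion=("motion", "first"))
        )
        obs = abs(per_trial.groupby("motion")["mad"].mean().diff().iloc[-1])
        rng = np.random.default_rng(3)
        labels = per_trial["motion"].to_numpy().copy()
        null = []
        for _ in range(500):
            rng.shuffle(labels)
            g = per_trial.groupby(labels)["mad"].mean()
            null.append(abs(g.iloc[1] - g.iloc[0]))
        assert obs <= np.quantile(null, 0.99)

    def test_report_structure_mirrors_study_tables(self, specimen, geometry):
        trials = _make_trials(specimen, geometry)
        report = stratified_report(trials, {specimen.specimen_id: specimen})
        assert set(report.analysis) == {"pooled", "bone", "specimen", "motion"}
        assert (report.groupby(["analysis", "stratum"])["dof"].count() == 6).all()
        assert report.loc[report.analysis == "pooled", "loa_ci"].notna().all()
        assert report.loc[report.analysis != "pooled", "loa_ci"].isna().all()

    def test_scale_equivariance(self, rng):
        d = rng.normal(0.2, 0.5, 500)
        k = -3.0
        base, scaled = bland_altman(d), bland_altman(k * d)
        assert scaled["bias"] == pytest.approx(k * base["bias"])
        assert scaled["loa"] == pytest.approx(abs(k) * base["loa"])
        mad0, _ = accuracy_mad(d)
        mad1, _ = accuracy_mad(k * d)
        assert mad1 == pytest.approx(abs(k) * mad0)
        assert loa_confidence_interval(abs(k) * base["sd"], 500) == pytest.approx(
            abs(k) * loa_confidence_interval(base["sd"], 500)
        )


class TestNullPipeline:
    def test_zero_noise_gives_zero_statistics_everywhere(self, specimen, geometry):
        trials = _make_trials(
            specimen, geometry, n_hop=1, n_drop=1,
            bead_pixel_noise_sd=0.0, model_rot_noise_sd=0.0,
            model_trans_noise_sd=0.0, outlier_frame_prob=0.0,
        )
        report = stratified_report(trials, {specimen.specimen_id: specimen})
        for col in ("mad", "bias", "loa", "outlier_frac"):
            assert np.abs(report[col].to_numpy()).max() < 1e-6, col
        assert np.abs(report["loa_ci"].dropna().to_numpy()).max() < 1e-6

    def test_common_frame_run_contiguous(self, specimen, geometry, quiet_trial_cfg):
        trial = simulate_trial(specimen, geometry, quiet_trial_cfg)
        emulate_trial_model(trial, specimen, quiet_trial_cfg, geometry.frame_rate_hz)
        track_trial(trial, {"femur": specimen.femur, "tibia": specimen.tibia}, geometry)
        run = common_frame_run(trial)
        assert len(run) > 0
        assert np.array_equal(run, np.arange(run[0], run[-1] + 1))
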