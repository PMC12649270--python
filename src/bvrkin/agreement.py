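"""Accuracy, bias, and precision of model-based vs. marker-based tracking.

Accuracy is the mean absolute difference (MAD ± SD) between the two
tracking methods per degree of freedom; bias and precision come from
Bland–Altman analysis, with precision tabulated as the limits-of-agreement
(LoA) half-width 1.96 × SD of the differences.  Differences are signed
model − marker (test minus reference).  Four stratifications mirror the
validation design: pooled, per bone, per specimen, and per motion type.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .kinematics import (
    DOF_COLUMNS,
    AnatomicalFrame,
    build_anatomical_frame,
    decompose_xyz,
    filter_pose_sequence,
    kinematics_table,
)
from .transforms import RigidTransform

__all__ = [
    "frame_differences",
    "accuracy_mad",
    "bland_altman",
    "loa_confidence_interval",
    "per_bone_differences",
    "compute_differences",
    "summarize_differences",
    "stratified_report",
    "common_frame_run",
    "bland_altman_plot",
]

LOA_MULTIPLIER = 1.96


def frame_differences(model: pd.DataFrame, marker: pd.DataFrame, **strata) -> pd.DataFrame:
    """Per-frame, per-DOF signed differences (model − marker) and pair means.

    Both tables must cover the same frames.  Returns a long-format table
    with columns ``frame, dof, diff, pair_mean`` plus any stratum labels
    given as keyword arguments.
    """
    fa = model["frame"].to_numpy()
    fb = marker["frame"].to_numpy()
    if len(fa) != len(fb) or not np.array_equal(fa, fb):
        missing = sorted(set(fa).symmetric_difference(fb))
        raise ValueError(f"frame mismatch between tables; unmatched frames: {missing[:20]}")
    parts = []
    for dof in DOF_COLUMNS:
        a = model[dof].to_numpy(float)
        b = marker[dof].to_numpy(float)
        parts.append(
            pd.DataFrame(
                {"frame": fa, "dof": dof, "diff": a - b, "pair_mean": (a + b) / 2.0}
            )
        )
    out = pd.concat(parts, ignore_index=True)
    for k, v in strata.items():
        out[k] = v
    return out


def accuracy_mad(diffs) -> tuple[float, float]:
    """Mean and SD of the absolute differences (the accuracy metric)."""
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    a = np.abs(d)
    return float(a.mean()), float(a.std(ddof=1))


def bland_altman(diffs) -> dict:
    """Bland–Altman bias, LoA half-width, and outlier fraction.

    ``bias`` is the mean signed difference; the LoA half-width is
    1.96 × sample SD (ddof=1); a frame is an outlier when its deviation
    from the bias exceeds the LoA half-width.  Deviations below 1e-9
    (°/mm) — far beneath any tracking resolution — are never counted as
    outliers, so numerically-zero difference sets report a zero fraction.
    """
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = LOA_MULTIPLIER * sd
    dev = np.abs(d - bias)
    outliers = (dev > loa) & (dev > 1e-9)
    return {
        "n": int(d.size),
        "bias": bias,
        "sd": sd,
        "loa": loa,
        "outlier_frac": float(outliers.mean()),
    }


def loa_confidence_interval(sd_diff: float, n: int) -> float:
    """Large-sample CI half-width for a limit of agreement.

    Classical approximation: SE(LoA) ≈ sqrt(3/n) × SD, so the 95% CI
    half-width is 1.96 × sqrt(3/n) × SD.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    return LOA_MULTIPLIER * np.sqrt(3.0 / n) * sd_diff


def per_bone_differences(
    marker_seq,
    model_seq,
    acs: AnatomicalFrame,
    frames=None,
    **strata,
) -> pd.DataFrame:
    """Single-bone tracking differences resolved in the bone's anatomical frame.

    For each frame the method-difference transform ``A ∘ (T_marker⁻¹ ∘
    T_model) ∘ A⁻¹`` is decomposed X-Y-Z into 6 DOF differences; a perfect
    agreement gives the identity and six zeros.
    """
    marker_seq, model_seq = list(marker_seq), list(model_seq)
    if len(marker_seq) != len(model_seq):
        raise ValueError("marker and model sequences differ in length")
    if frames is None:
        frames = np.arange(len(marker_seq))
    a = acs.transform
    ainv = a.inverse()
    rows = []
    for t_marker, t_model in zip(marker_seq, model_seq):
        delta = a @ t_marker.inverse() @ t_model @ ainv
        rows.append(decompose_xyz(delta))
    wide = pd.DataFrame(rows, columns=DOF_COLUMNS)
    parts = []
    for dof in DOF_COLUMNS:
        parts.append(
            pd.DataFrame(
                {
                    "frame": np.asarray(frames),
                    "dof": dof,
                    "diff": wide[dof].to_numpy(),
                    "pair_mean": np.nan,
                }
            )
        )
    out = pd.concat(parts, ignore_index=True)
    for k, v in strata.items():
        out[k] = v
    return out


def _summarize(diff_long: pd.DataFrame, analysis: str, stratum, with_ci: bool) -> pd.DataFrame:
    rows = []
    for dof in DOF_COLUMNS:
        d = diff_long.loc[diff_long["dof"] == dof, "diff"].to_numpy(float)
        mad, mad_sd = accuracy_mad(d)
        ba = bland_altman(d)
        rows.append(
            {
                "analysis": analysis,
                "stratum": stratum,
                "dof": dof,
                "n": ba["n"],
                "mad": mad,
                "mad_sd": mad_sd,
                "bias": ba["bias"],
                "loa": ba["loa"],
                "loa_ci": loa_confidence_interval(ba["sd"], ba["n"]) if with_ci else np.nan,
                "outlier_frac": ba["outlier_frac"],
            }
        )
    return pd.DataFrame(rows)


def common_frame_run(trial) -> np.ndarray:
    """Longest contiguous run of frames where both bones are tracked by both methods.

    Marker-based tracking drops frames with too few visible beads (typically
    while a bone enters or leaves the field of view); the analysis uses the
    longest uninterrupted stretch so that pose filtering sees uniformly
    sampled data.
    """
    ok = np.ones(trial.n_frames, dtype=bool)
    for bone in ("femur", "tibia"):
        for method in (trial.marker, trial.model):
            seq = method.get(bone)
            if seq is None:
                raise ValueError(f"trial {trial.trial_id}: no {bone} sequence")
            ok &= np.array([t is not None for t in seq])
    if not ok.any():
        return np.array([], dtype=int)
    # longest contiguous True run
    best, cur_start, best_span = 0, None, (0, 0)
    for i, v in enumerate(np.append(ok, False)):
        if v and cur_start is None:
            cur_start = i
        elif not v and cur_start is not None:
            if i - cur_start > best:
                best, best_span = i - cur_start, (cur_start, i)
            cur_start = None
    return np.arange(*best_span)


def compute_differences(
    trials,
    specimens: dict,
    frame_rate_hz: float = 250.0,
    filter_cutoff_hz: float = 10.0,
    min_frames: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame method differences for a set of tracked trials.

    For each trial, both methods' pose sequences are low-pass filtered on
    the common contiguous frame run, relative tibiofemoral kinematics are
    computed and differenced (joint table), and the per-bone transform
    differences are decomposed in each bone's anatomical frame (bone
    table).  Returns ``(joint_long, bone_long)``.
    """
    joint_parts, bone_parts = [], []
    for trial in trials:
        spec = specimens[trial.specimen_id]
        run = common_frame_run(trial)
        if len(run) < min_frames:
            warnings.warn(
                f"trial {trial.trial_id}: only {len(run)} usable frames; skipped"
            )
            continue
        acs_f = build_anatomical_frame(spec.femur)
        acs_t = build_anatomical_frame(spec.tibia)
        filtered = {}
        for method_name, store in (("marker", trial.marker), ("model", trial.model)):
            filtered[method_name] = {
                bone: filter_pose_sequence(
                    [store[bone][k] for k in run], frame_rate_hz, filter_cutoff_hz
                )
                for bone in ("femur", "tibia")
            }
        tables = {
            m: kinematics_table(
                filtered[m]["femur"], filtered[m]["tibia"], acs_f, acs_t,
                frame_rate_hz, frames=run,
            )
            for m in ("marker", "model")
        }
        joint_parts.append(
            frame_differences(
                tables["model"], tables["marker"],
                specimen=trial.specimen_id, motion=trial.motion, trial=trial.trial_id,
            )
        )
        for bone, acs in (("femur", acs_f), ("tibia", acs_t)):
            bone_parts.append(
                per_bone_differences(
                    filtered["marker"][bone], filtered["model"][bone], acs,
                    frames=run, bone=bone,
                    specimen=trial.specimen_id, motion=trial.motion, trial=trial.trial_id,
                )
            )
    if not joint_parts:
        raise ValueError("no trial had enough usable frames for analysis")
    return pd.concat(joint_parts, ignore_index=True), pd.concat(bone_parts, ignore_index=True)


def summarize_differences(joint: pd.DataFrame, bones: pd.DataFrame) -> pd.DataFrame:
    """Assemble the four stratified analyses from long difference tables."""
    reports = [_summarize(joint, "pooled", "all", with_ci=True)]
    for col, analysis, table in (
        ("bone", "bone", bones),
        ("specimen", "specimen", joint),
        ("motion", "motion", joint),
    ):
        for level in sorted(table[col].unique(), key=str):
            sub = table[table[col] == level]
            if sub.empty:
                warnings.warn(f"empty stratum {analysis}={level}; omitted")
                continue
            reports.append(_summarize(sub, analysis, level, with_ci=False))
    return pd.concat(reports, ignore_index=True)


def stratified_report(
    trials,
    specimens: dict,
    frame_rate_hz: float = 250.0,
    filter_cutoff_hz: float = 10.0,
    min_frames: int = 7,
) -> pd.DataFrame:
    """The four stratified agreement analyses over a set of tracked trials.

    (1) all data pooled, with LoA CIs; (2) femur and tibia separately via
    the per-bone transform differences; (3) by specimen; (4) by motion
    type.  Returns one tidy table with columns ``analysis, stratum, dof,
    n, mad, mad_sd, bias, loa, loa_ci, outlier_frac``.
    """
    joint, bones = compute_differences(
        trials, specimens, frame_rate_hz, filter_cutoff_hz, min_frames
    )
    return summarize_differences(joint, bones)


def bland_altman_plot(diff_long: pd.DataFrame, path, by: str = "specimen") -> None:
    """Grid of Bland–Altman plots (difference vs. pair mean) per stratum × DOF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = sorted(diff_long[by].unique(), key=str)
    fig, axes = plt.subplots(
        len(levels), len(DOF_COLUMNS),
        figsize=(3 * len(DOF_COLUMNS), 2.5 * len(levels)),
        squeeze=False,
    )
    for i, level in enumerate(levels):
        for j, dof in enumerate(DOF_COLUMNS):
            sub = diff_long[(diff_long[by] == level) & (diff_long["dof"] == dof)]
            ax = axes[i][j]
            d = sub["diff"].to_numpy(float)
            ba = bland_altman(d)
            ax.scatter(sub["pair_mean"], d, s=4, alpha=0.4)
            ax.axhline(ba["bias"], color="k", lw=1)
            for sgn in (-1, 1):
                ax.axhline(ba["bias"] + sgn * ba["loa"], color="k", ls="--", lw=0.8)
            if i == 0:
                ax.set_title(dof)
            if j == 0:
                ax.set_ylabel(f"{by} {level}\ndiff (°/mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
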