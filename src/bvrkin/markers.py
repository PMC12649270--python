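"""Gold-standard marker-based pose reconstruction from biplane bead views.

Two-view triangulation (linear least squares on the back-projected rays)
followed by rigid registration of the CT bead model onto the triangulated
lab positions.  No bundle adjustment: with two calibrated views and a rigid
scene the linear solution is already at the noise floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scene import BVRGeometry, BoneModel, TrackedTrial
from .transforms import PointSet, RigidTransform, kabsch_fit

__all__ = ["triangulate", "fit_bone_pose", "track_trial", "RayConditioningError"]


class RayConditioningError(ValueError):
    """Raised when the two back-projected rays are too close to parallel."""


def _backproject(view, u: float, v: float):
    """Pixel coordinates -> (source, unit ray direction) in the lab frame."""
    p = (
        view.detector_center
        + u * view.pixel_pitch * view.detector_axes[0]
        + v * view.pixel_pitch * view.detector_axes[1]
    )
    d = p - view.source_position
    return view.source_position, d / np.linalg.norm(d)


def triangulate(obs_view1, obs_view2, geometry: BVRGeometry):
    """Intersect the two back-projected rays in a least-squares sense.

    Parameters are ``(u, v)`` pixel observations of one bead in each view.
    Returns ``(point_mm, reprojection_residual_px)`` where the residual is
    the RMS pixel distance between the observations and the reprojection of
    the recovered point.

    Raises
    ------
    RayConditioningError
        If the rays subtend less than 1°, where the intersection is
        ill-conditioned along the viewing direction.
    """
    s1, d1 = _backproject(geometry.views[0], *obs_view1)
    s2, d2 = _backproject(geometry.views[1], *obs_view2)
    angle = np.degrees(np.arccos(np.clip(abs(d1 @ d2), -1.0, 1.0)))
    if angle < 1.0:
        raise RayConditioningError(
            f"rays subtend only {angle:.3f}° (< 1°); triangulation is ill-conditioned"
        )
    # sum_i (I - d_i d_i^T) (p - s_i) = 0
    a = np.zeros((3, 3))
    b = np.zeros(3)
    for s, d in ((s1, d1), (s2, d2)):
        m = np.eye(3) - np.outer(d, d)
        a += m
        b += m @ s
    point = np.linalg.solve(a, b)

    from .scene import project_beads

    uv, _ = project_beads(geometry, point[None, :])
    res = np.array([uv[0, 0] - np.asarray(obs_view1), uv[1, 0] - np.asarray(obs_view2)])
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return point, rms


def fit_bone_pose(
    bone: BoneModel,
    triangulated: PointSet,
    min_beads: int = 3,
):
    """Rigid fit of the CT bead model onto triangulated lab positions.

    Returns ``(RigidTransform CT -> lab, rms_residual_mm)`` or ``None`` when
    fewer than ``min_beads`` beads were triangulated for the frame, marking
    it untrackable for this bone.
    """
    if len(triangulated) < min_beads:
        return None
    if triangulated.frame != "lab":
        raise ValueError("triangulated points must be in the lab frame")
    ct = bone.beads.subset(triangulated.labels)
    return kabsch_fit(ct, triangulated)


def track_trial(
    trial: TrackedTrial,
    bones: dict,
    geometry: BVRGeometry,
    min_beads: int = 3,
) -> TrackedTrial:
    """Fill ``trial.marker`` from the trial's 2D bead observations.

    For every frame and bone, beads visible in *both* views are triangulated
    and the bone pose fit; frames with fewer than ``min_beads`` such beads
    yield ``None`` (untrackable) and shrink downstream frame counts.
    """
    obs = trial.observations
    if obs is None:
        raise ValueError("trial has no bead observations")
    for bone_name, bone in bones.items():
        labels = set(bone.beads.labels)
        seq: list[RigidTransform | None] = []
        bone_obs = obs[obs["bead_label"].isin(labels)]
        by_frame = dict(tuple(bone_obs.groupby("frame")))
        for k in trial.frames:
            fr = by_frame.get(k)
            pts, labs = [], []
            if fr is not None:
                vis = fr[fr["visible"]]
                v1 = vis[vis["view"] == 1].set_index("bead_label")
                v2 = vis[vis["view"] == 2].set_index("bead_label")
                for label in v1.index.intersection(v2.index):
                    p, _ = triangulate(
                        (v1.at[label, "u"], v1.at[label, "v"]),
                        (v2.at[label, "u"], v2.at[label, "v"]),
                        geometry,
                    )
                    pts.append(p)
                    labs.append(label)
            if len(pts) >= min_beads:
                fit = fit_bone_pose(bone, PointSet(tuple(labs), np.array(pts), frame="lab"), min_beads)
                seq.append(fit[0] if fit is not None else None)
            else:
                seq.append(None)
        trial.marker[bone_name] = seq
    return trial
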