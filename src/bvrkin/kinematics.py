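"""Six-degree-of-freedom joint kinematics from tracked bone poses.

Pose sequences are low-pass filtered on their quaternion and translation
components, expressed as the tibia moving in the femoral anatomical frame,
and decomposed with an X-Y-Z Euler sequence into flexion/extension (FE),
abduction/adduction (AA), internal/external rotation (IE) in degrees and
medial/lateral (ML), anterior/posterior (AP), inferior/superior (IS)
translations in mm on the femoral anatomical axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .scene import BoneModel
from .transforms import RigidTransform, UnitQuaternion, hemisphere_align

__all__ = [
    "AnatomicalFrame",
    "build_anatomical_frame",
    "filter_pose_sequence",
    "relative_pose",
    "decompose_xyz",
    "recompose_xyz",
    "tibial_speed",
    "time_normalize",
    "kinematics_table",
    "DOF_COLUMNS",
    "GimbalLockError",
]

DOF_COLUMNS = ["FE", "AA", "IE", "ML", "AP", "IS"]

# Zero-phase forward-backward filtering doubles the effective order and
# shifts the -3 dB point; dividing the design cutoff by (2^(1/2)-1)^(1/4)
# restores the nominal cutoff (standard dual-pass correction).
_DUAL_PASS_CORRECTION = (np.sqrt(2.0) - 1.0) ** 0.25


def _odd_reflect(arr: np.ndarray, pad: int) -> tuple[np.ndarray, int]:
    """Antisymmetric (odd) end-point reflection along axis 0.

    Extends a linear trend exactly; applied repeatedly when the requested
    pad exceeds the available length.  Returns (padded, samples added per
    side).
    """
    out = arr
    added = 0
    while added < pad:
        l = min(pad - added, out.shape[0] - 1)
        left = 2 * out[0] - out[1:l + 1][::-1]
        right = 2 * out[-1] - out[-l - 1:-1][::-1]
        out = np.concatenate([left, out, right], axis=0)
        added += l
    return out, added


class GimbalLockError(ValueError):
    """Raised when the Y rotation approaches ±90° and X/Z become degenerate."""


@dataclass(frozen=True)
class AnatomicalFrame:
    """Transform from a bone's CT coordinates to its anatomical frame.

    Axes: X = flexion axis (through the condylar/plateau landmarks),
    Z = long axis of the shaft (superior positive), Y = Z x X.
    """

    bone: str
    transform: RigidTransform


_LANDMARK_SETS = {
    "femur": ("medial_epicondyle", "lateral_epicondyle", "proximal_shaft"),
    "tibia": ("medial_plateau", "lateral_plateau", "distal_shaft"),
}


def build_anatomical_frame(bone: BoneModel | None = None, *, name: str = None, landmarks: dict = None) -> AnatomicalFrame:
    """Construct the anatomical frame from paired + shaft landmarks.

    The origin sits midway between the paired (medial/lateral) landmarks;
    X runs medial -> lateral; the shaft landmark fixes the superior
    direction of the long axis (the femoral shaft point is proximal/above,
    the tibial one distal/below); Y completes a right-handed triad.
    """
    if bone is not None:
        name, landmarks = bone.name, bone.landmarks
    if name not in _LANDMARK_SETS:
        raise ValueError(f"unknown bone {name!r}")
    keys = _LANDMARK_SETS[name]
    missing = [k for k in keys if k not in landmarks]
    if missing:
        raise ValueError(f"{name}: missing landmarks {missing}")
    med, lat, shaft = (np.asarray(landmarks[k], float) for k in keys)
    origin = (med + lat) / 2.0
    x = lat - med
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError(f"{name}: paired landmarks coincide")
    x = x / nx
    z_raw = (shaft - origin) if name == "femur" else (origin - shaft)
    if np.linalg.norm(np.cross(z_raw, x)) < 1e-9:
        raise ValueError(f"{name}: shaft landmark is collinear with the condylar axis")
    y = np.cross(z_raw, x)
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    rot = np.stack([x, y, z])   # rows: anatomical axes in CT coordinates
    return AnatomicalFrame(name, RigidTransform(rot, -rot @ origin))


def filter_pose_sequence(
    transforms,
    frame_rate_hz: float = 250.0,
    cutoff_hz: float = 10.0,
    order: int = 2,
    zero_phase: bool = True,
) -> list[RigidTransform]:
    """Low-pass filter a pose sequence on quaternion + translation components.

    Rotations are converted to quaternions, hemisphere-aligned so the four
    components are continuous, each component (and each translation axis)
    Butterworth-filtered, quaternions renormalised, and poses rebuilt.  The
    default is a zero-phase forward-backward pass of the 2nd-order design
    with a dual-pass cutoff correction; ``zero_phase=False`` gives a causal
    single pass at the nominal cutoff.
    """
    transforms = list(transforms)
    n = len(transforms)
    min_n = 3 * order + 1
    if n < min_n:
        raise ValueError(
            f"pose sequence of {n} frames is too short to filter; "
            f"need at least {min_n} frames for an order-{order} filter"
        )
    qs = hemisphere_align([t.to_quaternion() for t in transforms])
    qarr = np.stack([q.as_array() for q in qs])                 # (n, 4)
    tarr = np.stack([t.translation for t in transforms])        # (n, 3)
    if zero_phase:
        wn = cutoff_hz / _DUAL_PASS_CORRECTION / (frame_rate_hz / 2.0)
        b, a = signal.butter(order, min(wn, 0.99))
        # reflect the data well past the filter's settling time so the
        # forward-backward transients decay outside the kept region; the
        # built-in padding is capped at n-1, far too short for sequences
        # near the minimum length (e.g. 10-frame drop trials)
        pad = int(np.ceil(4.0 * frame_rate_hz / cutoff_hz))
        arr = np.concatenate([qarr, tarr], axis=1)
        padded, added = _odd_reflect(arr, pad)
        filt = signal.filtfilt(b, a, padded, axis=0, padlen=min(9, padded.shape[0] - 1))
        filt = filt[added:added + n]
        qf, tf = filt[:, :4], filt[:, 4:]
    else:
        wn = cutoff_hz / (frame_rate_hz / 2.0)
        b, a = signal.butter(order, min(wn, 0.99))
        zi = signal.lfilter_zi(b, a)
        qf = np.stack([signal.lfilter(b, a, qarr[:, j], zi=zi * qarr[0, j])[0] for j in range(4)], axis=1)
        tf = np.stack([signal.lfilter(b, a, tarr[:, j], zi=zi * tarr[0, j])[0] for j in range(3)], axis=1)
    qf = qf / np.linalg.norm(qf, axis=1, keepdims=True)
    out = []
    for k in range(n):
        q = UnitQuaternion(*qf[k])
        out.append(RigidTransform.from_quaternion(q, tf[k]))
    return out


def relative_pose(
    femur_pose: RigidTransform,
    tibia_pose: RigidTransform,
    femur_acs: AnatomicalFrame,
    tibia_acs: AnatomicalFrame,
) -> RigidTransform:
    """Pose of the tibial anatomical frame expressed in the femoral one.

    Composition: ``A_f ∘ T_f⁻¹ ∘ T_t ∘ A_t⁻¹`` where ``T`` are CT -> lab
    bone poses and ``A`` are CT -> anatomical transforms.  Identical bone
    poses with identical anatomical frames therefore give the identity.
    """
    return (
        femur_acs.transform
        @ femur_pose.inverse()
        @ tibia_pose
        @ tibia_acs.transform.inverse()
    )


def decompose_xyz(relative: RigidTransform):
    """X-Y-Z Euler decomposition into (FE, AA, IE, ML, AP, IS).

    Angles are degrees such that ``R = Rx(FE) @ Ry(AA) @ Rz(IE)``;
    translations are the relative-pose translation components on the femoral
    anatomical axes (ML = X, AP = Y, IS = Z), in mm.

    Raises
    ------
    GimbalLockError
        When ``|cos AA| < 1e-6`` (AA within ~0.00006° of ±90°).
    """
    r = relative.rotation
    sy = np.clip(r[0, 2], -1.0, 1.0)
    cy = np.sqrt(max(0.0, 1.0 - sy * sy))
    if cy < 1e-6:
        raise GimbalLockError("abduction angle at ±90°: FE and IE are not separable")
    aa = np.arcsin(sy)
    fe = np.arctan2(-r[1, 2], r[2, 2])
    ie = np.arctan2(-r[0, 1], r[0, 0])
    ml, ap, is_ = relative.translation
    return (
        float(np.degrees(fe)),
        float(np.degrees(aa)),
        float(np.degrees(ie)),
        float(ml),
        float(ap),
        float(is_),
    )


def recompose_xyz(fe_deg, aa_deg, ie_deg, ml=0.0, ap=0.0, is_=0.0) -> RigidTransform:
    """Inverse of :func:`decompose_xyz` (used as its reconstruction check)."""
    fe, aa, ie = np.radians([fe_deg, aa_deg, ie_deg])

    def rx(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    return RigidTransform(rx(fe) @ ry(aa) @ rz(ie), [ml, ap, is_])


def tibial_speed(tibia_transforms, frame_rate_hz: float, origin_ct=(0.0, 0.0, 0.0)):
    """Per-frame linear speed (m/s) of a tibial point, plus the trial mean.

    The tracked point (default: the tibial anatomical origin expressed in CT
    coordinates) is mapped to the lab frame each frame and differentiated
    with central differences (one-sided at the ends).
    """
    transforms = list(tibia_transforms)
    if len(transforms) < 2:
        raise ValueError("need at least 2 frames to differentiate")
    p = np.stack([t.apply(np.asarray(origin_ct, float)) for t in transforms])  # mm
    v = np.gradient(p, axis=0) * frame_rate_hz / 1000.0    # m/s per axis
    speed = np.linalg.norm(v, axis=1)
    return speed, float(speed.mean())


def time_normalize(table: pd.DataFrame, n_frames: int) -> pd.DataFrame:
    """Linearly resample a kinematics table onto ``n_frames`` equal steps.

    Numeric columns are interpolated onto ``n_frames`` equally spaced points
    spanning the trial (endpoints preserved exactly); non-numeric metadata
    columns are carried through unchanged.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 input frames to normalize")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    x_in = np.arange(len(table), dtype=float)
    x_out = np.linspace(0.0, x_in[-1], n_frames)
    out = {}
    for col in table.columns:
        if col == "frame":
            out[col] = np.arange(n_frames)
        elif pd.api.types.is_numeric_dtype(table[col]):
            out[col] = np.interp(x_out, x_in, table[col].to_numpy(float))
        else:
            vals = table[col].unique()
            out[col] = np.repeat(vals[0], n_frames) if len(vals) == 1 else np.nan
    return pd.DataFrame(out)


def kinematics_table(
    femur_seq,
    tibia_seq,
    femur_acs: AnatomicalFrame,
    tibia_acs: AnatomicalFrame,
    frame_rate_hz: float,
    frames=None,
    **metadata,
) -> pd.DataFrame:
    """Per-frame 6-DOF joint kinematics table with tibial speed.

    One row per frame with columns ``frame, FE, AA, IE, ML, AP, IS, speed``
    plus any metadata keyword columns (method, specimen, trial, motion...).
    """
    femur_seq, tibia_seq = list(femur_seq), list(tibia_seq)
    if len(femur_seq) != len(tibia_seq):
        raise ValueError("femur and tibia sequences differ in length")
    rows = [
        decompose_xyz(relative_pose(f, t, femur_acs, tibia_acs))
        for f, t in zip(femur_seq, tibia_seq)
    ]
    df = pd.DataFrame(rows, columns=DOF_COLUMNS)
    df.insert(0, "frame", np.arange(len(df)) if frames is None else np.asarray(frames))
    origin_ct = tibia_acs.transform.inverse().apply(np.zeros(3))
    if len(tibia_seq) >= 2:
        speed, _ = tibial_speed(tibia_seq, frame_rate_hz, origin_ct)
        df["speed"] = speed
    else:
        df["speed"] = np.nan
    for k, v in metadata.items():
        df[k] = v
    return df
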