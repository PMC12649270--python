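"""Rigid-body algebra, quaternions, and point-set registration.

Conventions
-----------
* Rotations are 3x3 proper orthonormal matrices; translations are in mm.
* A :class:`RigidTransform` maps points from its *source* frame to its
  *target* frame: ``p_target = R @ p_source + t``.  Bone poses map CT
  coordinates to the lab (biplane radiography) coordinate system.
* Quaternions are scalar-first ``(w, x, y, z)`` and unit norm.  ``q`` and
  ``-q`` encode the same rotation (double cover).
* Angles are radians internally; public reporting layers convert to degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "UnitQuaternion",
    "PointSet",
    "kabsch_fit",
    "hemisphere_align",
    "DegenerateGeometryError",
]

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a point configuration cannot support a rigid fit."""


def _check_rotation(r: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {r.shape}")
    err = np.abs(r.T @ r - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"rotation is not orthonormal (max |R^T R - I| = {err:.3g})")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation has determinant -1 (reflection, not a rotation)")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("bottom row of homogeneous matrix must be [0,0,0,1]")
        return RigidTransform(m[:3, :3], m[:3, 3])

    @staticmethod
    def from_rotvec(rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Axis-angle (radians) constructor, mostly for tests and noise models."""
        return RigidTransform(
            Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
            np.asarray(translation, float),
        )

    # -- algebra -----------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or a stack (N, 3) from source to target frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    # -- quaternions -------------------------------------------------
    def to_quaternion(self) -> "UnitQuaternion":
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        return UnitQuaternion(w, x, y, z)

    @staticmethod
    def from_quaternion(q: "UnitQuaternion", translation) -> "RigidTransform":
        return RigidTransform(q.as_matrix(), np.asarray(translation, float))

    # -- comparison --------------------------------------------------
    def is_close(self, other: "RigidTransform", rtol: float = 0.0, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, rtol=rtol, atol=atol)
            and np.allclose(self.translation, other.translation, rtol=rtol, atol=atol)
        )

    def rotation_angle(self) -> float:
        """Magnitude of the rotation in radians."""
        return float(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ang = np.degrees(self.rotation_angle())
        return f"RigidTransform(angle={ang:.3f}°, t={np.array2string(self.translation, precision=3)})"


@dataclass(frozen=True)
class UnitQuaternion:
    """Scalar-first unit quaternion."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        n = float(np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2))
        if n < 1e-12:
            raise ValueError("zero-norm quaternion")
        if abs(n - 1.0) > _ORTHO_TOL:
            # normalize softly: allow inputs a hair off unit norm
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"quaternion norm {n} too far from 1")
            object.__setattr__(self, "w", self.w / n)
            object.__setattr__(self, "x", self.x / n)
            object.__setattr__(self, "y", self.y / n)
            object.__setattr__(self, "z", self.z / n)

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def as_matrix(self) -> np.ndarray:
        return Rotation.from_quat([self.x, self.y, self.z, self.w]).as_matrix()

    def __neg__(self) -> "UnitQuaternion":
        return UnitQuaternion(-self.w, -self.x, -self.y, -self.z)

    def dot(self, other: "UnitQuaternion") -> float:
        return float(self.as_array() @ other.as_array())


@dataclass(frozen=True)
class PointSet:
    """Labelled 3D points (mm) tagged with their coordinate frame (``CT`` or ``lab``)."""

    labels: tuple
    coordinates: np.ndarray
    frame: str = "CT"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        labels = tuple(self.labels)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (N, 3), got {coords.shape}")
        if len(labels) != coords.shape[0]:
            raise ValueError("labels and coordinates length mismatch")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate bead labels")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    def subset(self, labels) -> "PointSet":
        idx = [self.labels.index(l) for l in labels]
        return PointSet(tuple(labels), self.coordinates[idx], self.frame)


def kabsch_fit(source: PointSet, target: PointSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration of matched point sets (Kabsch, SVD).

    Finds the transform ``T`` minimising ``sum_i ||T(source_i) - target_i||^2``
    over proper rotations, with the determinant-sign correction guarding
    against reflections.  Returns ``(T, rms_residual_mm)``.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or a collinear configuration.
    ValueError
        Label sets differ.
    """
    if set(source.labels) != set(target.labels):
        raise ValueError("source and target bead label sets differ")
    # reorder target to match source labels
    tgt = target.subset(source.labels)
    a = source.coordinates
    b = tgt.coordinates
    n = a.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 matched points, got {n}")
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    # collinearity: second principal extent of the source cloud ~ 0
    sv = np.linalg.svd(ca, compute_uv=False)
    if sv[1] < 1e-6:
        raise DegenerateGeometryError(
            "point configuration is collinear (second singular value "
            f"{sv[1]:.3g} mm); rigid fit is under-determined"
        )
    h = ca.T @ cb
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = b.mean(axis=0) - r @ a.mean(axis=0)
    fit = RigidTransform(r, t)
    resid = fit.apply(a) - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return fit, rms


def hemisphere_align(quaternions) -> list[UnitQuaternion]:
    """Flip quaternion signs so consecutive dot products are non-negative.

    The represented rotations are unchanged (q and -q are the same rotation);
    this removes sign discontinuities so the four components can be low-pass
    filtered as ordinary scalar time series.
    """
    qs = list(quaternions)
    if not qs:
        raise ValueError("empty quaternion sequence")
    out = [qs[0]]
    for q in qs[1:]:
        out.append(-q if out[-1].dot(q) < 0.0 else q)
    return out
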