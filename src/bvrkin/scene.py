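"""Synthetic biplane-videoradiography scene generation.

Everything the cadaver experiment provided is emulated here: a frozen
femur+tibia specimen carrying implanted tantalum beads, a two-view X-ray
geometry (source-to-image distance ~185 cm, 55° separation, 250 Hz), rigid
hop/drop trajectories through a finite field of view, per-frame 2D bead
projections with pixel noise, and a noise-model stand-in for intensity-based
2D-3D model registration.

The central premise: the specimen is rigidly frozen, so the tibia-relative-
to-femur pose is constant across every frame of every trial, and any
apparent relative motion recovered downstream is tracking error by
construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .transforms import PointSet, RigidTransform

__all__ = [
    "ViewModel",
    "BVRGeometry",
    "BoneModel",
    "SpecimenConfig",
    "TrialConfig",
    "TrackedTrial",
    "build_geometry",
    "generate_specimen",
    "generate_trajectory",
    "project_beads",
    "emulate_model_based",
    "soft_tissue_volume",
    "mask_beads",
    "simulate_trial",
    "emulate_trial_model",
    "SPECIMEN_SOFT_TISSUE_CM3",
]

# Soft-tissue volumes of the three specimen presets (cm^3).
SPECIMEN_SOFT_TISSUE_CM3 = {1: 3038.0, 2: 1203.0, 3: 3964.0}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewModel:
    """Single pinhole-style X-ray view: point source and flat detector.

    Detector (u, v) coordinates are in pixels relative to the principal
    point (the detector centre); u along ``detector_axes[0]``, v along
    ``detector_axes[1]``.
    """

    source_position: np.ndarray      # mm, lab frame
    detector_center: np.ndarray      # mm, lab frame
    detector_axes: np.ndarray        # (2, 3) orthonormal, in detector plane
    detector_size: tuple             # (width, height) mm
    pixel_pitch: float               # mm / pixel

    def __post_init__(self) -> None:
        s = np.asarray(self.source_position, float).reshape(3)
        c = np.asarray(self.detector_center, float).reshape(3)
        ax = np.asarray(self.detector_axes, float).reshape(2, 3)
        object.__setattr__(self, "source_position", s)
        object.__setattr__(self, "detector_center", c)
        object.__setattr__(self, "detector_axes", ax)
        ray = self.ray_direction
        g = ax @ ax.T
        if np.abs(g - np.eye(2)).max() > 1e-9:
            raise ValueError("detector axes are not orthonormal")
        if np.abs(ax @ ray).max() > 1e-9:
            raise ValueError("detector axes are not orthogonal to the central ray")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def sid(self) -> float:
        """Source-to-image distance, mm."""
        return float(np.linalg.norm(self.detector_center - self.source_position))

    @property
    def ray_direction(self) -> np.ndarray:
        """Unit vector from source to detector centre."""
        d = self.detector_center - self.source_position
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class BVRGeometry:
    """Two calibrated X-ray views plus the shared frame rate."""

    views: tuple
    separation_angle_deg: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if len(self.views) != 2:
            raise ValueError("BVRGeometry needs exactly two views")
        measured = self.measured_separation_deg()
        if abs(measured - self.separation_angle_deg) > 0.01:
            raise ValueError(
                f"configured separation {self.separation_angle_deg}° does not match "
                f"measured inter-ray angle {measured:.4f}°"
            )
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate must be positive")

    def measured_separation_deg(self) -> float:
        d1 = self.views[0].ray_direction
        d2 = self.views[1].ray_direction
        return float(np.degrees(np.arccos(np.clip(d1 @ d2, -1.0, 1.0))))


def build_geometry(
    sid_mm: float = 1850.0,
    separation_deg: float = 55.0,
    frame_rate_hz: float = 250.0,
    detector_size_mm: tuple = (450.0, 450.0),
    pixel_pitch_mm: float = 0.45,
    source_to_iso_mm: float = 1400.0,
) -> BVRGeometry:
    """Symmetric two-view geometry about the lab origin (the isocentre).

    Both central rays lie in the horizontal X-Y plane, bisected by +Y; the
    lab +Z axis is vertical (drop direction is -Z, hop travel is +X).
    """
    if sid_mm <= 0:
        raise ValueError("SID must be positive")
    if not 0.0 < separation_deg < 180.0:
        raise ValueError("separation angle must be in (0, 180)°")
    if not 0.0 < source_to_iso_mm < sid_mm:
        raise ValueError("isocentre must lie between source and detector")
    half = np.radians(separation_deg / 2.0)
    views = []
    for sgn in (-1.0, +1.0):
        d = np.array([sgn * np.sin(half), np.cos(half), 0.0])
        source = -source_to_iso_mm * d
        center = source + sid_mm * d
        ex = np.cross([0.0, 0.0, 1.0], d)
        ex = ex / np.linalg.norm(ex)
        ey = np.cross(d, ex)
        views.append(
            ViewModel(source, center, np.stack([ex, ey]), tuple(detector_size_mm), pixel_pitch_mm)
        )
    if np.linalg.norm(views[0].source_position - views[1].source_position) < 1e-6:
        raise ValueError("degenerate geometry: the two sources coincide")
    return BVRGeometry(tuple(views), separation_deg, frame_rate_hz)


# ---------------------------------------------------------------------------
# specimen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoneModel:
    name: str
    beads: PointSet                 # CT frame, mm
    landmarks: dict                 # name -> (3,) CT frame, mm
    bead_diameter_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("femur", "tibia"):
            raise ValueError("bone name must be 'femur' or 'tibia'")
        n = len(self.beads)
        if not 6 <= n <= 8:
            raise ValueError(f"bead count must be in [6, 8], got {n}")


@dataclass(frozen=True)
class SpecimenConfig:
    specimen_id: int
    femur: BoneModel
    tibia: BoneModel
    frozen_relative_pose: RigidTransform   # tibia-CT -> femur-CT, constant
    flexion_deg: float
    soft_tissue_volume_cm3: float
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 20.0 <= self.flexion_deg <= 55.0:
            raise ValueError("flexion must lie in [20, 55]°")


def _sample_bead_cloud(rng, n, lo, hi, min_dist=5.0, min_thickness=1.0):
    """Rejection-sample n beads in a box, non-degenerate for rigid fitting."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    for _ in range(1000):
        pts = rng.uniform(lo, hi, size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if d[np.triu_indices(n, 1)].min() <= min_dist:
            continue
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[2] <= min_thickness:   # nearly coplanar
            continue
        return pts
    raise RuntimeError("bead cloud sampling failed to satisfy separation constraints")


def _random_rigid(rng, max_angle_deg, max_trans_mm) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0.0, max_angle_deg))
    t = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
    return RigidTransform.from_rotvec(ang * axis, t)


def generate_specimen(
    seed: int,
    soft_tissue_volume_cm3: float | None = None,
    specimen_id: int = 1,
    noise_scale: float = 1.0,
) -> SpecimenConfig:
    """Randomly generate a frozen femur+tibia specimen.

    Each bone carries 6-8 one-millimetre beads press-fit into cortical bone,
    expressed in its own CT coordinate system (a random rigid offset from the
    bone's anatomical template, as a real CT scan's axes would be).  The two
    bones are locked at a fixed relative pose with flexion drawn from the
    20-55° range of a hop-landing posture.
    """
    from .kinematics import build_anatomical_frame  # local import: no cycle at module load

    rng = np.random.default_rng(seed)
    if soft_tissue_volume_cm3 is None:
        soft_tissue_volume_cm3 = SPECIMEN_SOFT_TISSUE_CM3.get(specimen_id, 2500.0)

    # anatomical templates (mm): origin between paired landmarks, long axis ~Z
    femur_landmarks_t = {
        "medial_epicondyle": np.array([-40.0, 0.0, 0.0]),
        "lateral_epicondyle": np.array([40.0, 0.0, 0.0]),
        "proximal_shaft": np.array([0.0, 4.0, 180.0]),
    }
    tibia_landmarks_t = {
        "medial_plateau": np.array([-35.0, 0.0, 0.0]),
        "lateral_plateau": np.array([35.0, 0.0, 0.0]),
        "distal_shaft": np.array([0.0, 3.0, -250.0]),
    }
    bones = {}
    for name, lms, zlo, zhi in (
        ("femur", femur_landmarks_t, 5.0, 75.0),
        ("tibia", tibia_landmarks_t, -75.0, -5.0),
    ):
        n_beads = int(rng.integers(6, 9))
        cloud = _sample_bead_cloud(rng, n_beads, (-32.0, -28.0, zlo), (32.0, 28.0, zhi))
        ct_offset = _random_rigid(rng, max_angle_deg=25.0, max_trans_mm=20.0)
        beads_ct = ct_offset.apply(cloud)
        labels = tuple(f"{name[0]}{i + 1}" for i in range(n_beads))
        landmarks_ct = {k: ct_offset.apply(v) for k, v in lms.items()}
        bones[name] = BoneModel(name, PointSet(labels, beads_ct, frame="CT"), landmarks_ct)

    flexion = float(rng.uniform(20.0, 55.0))
    aa = float(rng.uniform(-3.0, 3.0))
    ie = float(rng.uniform(-3.0, 3.0))
    joint_rot = (
        Rotation.from_euler("X", flexion, degrees=True)
        * Rotation.from_euler("Y", aa, degrees=True)
        * Rotation.from_euler("Z", ie, degrees=True)
    ).as_matrix()
    joint_trans = np.array([
        rng.uniform(-2.0, 2.0),
        rng.uniform(-2.0, 2.0),
        -40.0 + rng.uniform(-5.0, 5.0),
    ])
    joint = RigidTransform(joint_rot, joint_trans)   # tibia-anat in femur-anat
    acs_f = build_anatomical_frame(bones["femur"])
    acs_t = build_anatomical_frame(bones["tibia"])
    frozen = acs_f.transform.inverse() @ joint @ acs_t.transform
    return SpecimenConfig(
        specimen_id=specimen_id,
        femur=bones["femur"],
        tibia=bones["tibia"],
        frozen_relative_pose=frozen,
        flexion_deg=flexion,
        soft_tissue_volume_cm3=float(soft_tissue_volume_cm3),
        noise_scale=noise_scale,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def generate_trajectory(
    motion: str,
    speed_mps: float,
    duration_s: float,
    frame_rate_hz: float,
    seed: int,
    wobble_mm: float = 3.0,
    wobble_deg: float = 2.0,
) -> list[RigidTransform]:
    """Rigid femur trajectory through the field of view.

    ``hop``: predominantly horizontal travel along +X with a small vertical
    oscillation; ``drop``: near free-fall vertical travel along -Z.  The path
    is centred on the lab origin.  Orientation wanders smoothly by at most a
    few degrees, as a hand-guided specimen would.  ``speed_mps == 0`` yields
    a perfectly stationary trial; ``wobble_mm = wobble_deg = 0`` yields an
    exactly constant-velocity segment.
    """
    if motion not in ("hop", "drop"):
        raise ValueError("motion must be 'hop' or 'drop'")
    n = int(round(duration_s * frame_rate_hz))
    if n < 2:
        raise ValueError("duration * frame_rate must give at least 2 frames")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / frame_rate_hz
    direction = np.array([1.0, 0.0, 0.0]) if motion == "hop" else np.array([0.0, 0.0, -1.0])
    # deterministic draw order keeps seeds reproducible regardless of speed
    perp = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]) if motion == "hop" else np.eye(3)[:2]
    amp = rng.uniform(0.3, 1.0, size=2) * wobble_mm
    freq = rng.uniform(1.0, 3.0, size=2)
    phase = rng.uniform(0.0, 2 * np.pi, size=2)
    rot_amp = np.radians(rng.uniform(0.3, 1.0, size=3) * wobble_deg)
    rot_freq = rng.uniform(0.5, 2.0, size=3)
    rot_phase = rng.uniform(0.0, 2 * np.pi, size=3)
    base_rotvec = np.radians(rng.uniform(-3.0, 3.0, size=3))

    if speed_mps == 0.0:
        pose = RigidTransform.from_rotvec(base_rotvec, np.zeros(3))
        return [pose] * n

    v_mm = speed_mps * 1000.0
    travel = v_mm * t
    pos = direction[None, :] * (travel - travel[-1] / 2.0)[:, None]
    for k in range(2):
        pos += perp[k][None, :] * (amp[k] * np.sin(2 * np.pi * freq[k] * t + phase[k]))[:, None]
    rotvecs = base_rotvec[None, :] + np.stack(
        [rot_amp[k] * np.sin(2 * np.pi * rot_freq[k] * t + rot_phase[k]) for k in range(3)],
        axis=1,
    )
    mats = Rotation.from_rotvec(rotvecs).as_matrix()
    return [RigidTransform(mats[i], pos[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_beads(
    geometry: BVRGeometry,
    points_lab: np.ndarray,
    pixel_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Perspective-project lab-frame points onto both detectors.

    Returns ``(uv, visible)`` with ``uv`` of shape (2, N, 2) pixels (view,
    point, [u, v]) and ``visible`` of shape (2, N) bool.  Points behind (or
    at) the source, or landing outside the detector bounds, are flagged not
    visible; Gaussian pixel noise is added to visible projections only.
    Invisible points carry NaN coordinates.
    """
    pts = np.atleast_2d(np.asarray(points_lab, float))
    if pixel_noise_sd > 0 and rng is None:
        raise ValueError("rng required when pixel_noise_sd > 0")
    uv = np.full((2, pts.shape[0], 2), np.nan)
    visible = np.zeros((2, pts.shape[0]), dtype=bool)
    for i, view in enumerate(geometry.views):
        s = view.source_position
        nrm = view.ray_direction
        rel = pts - s
        depth = rel @ nrm
        ok = depth > 1e-6
        # intersection of the source->point ray with the detector plane
        scale = np.where(ok, view.sid / np.where(ok, depth, 1.0), np.nan)
        hit = s + rel * scale[:, None]
        local = (hit - view.detector_center) @ view.detector_axes.T   # mm in-plane
        u = local[:, 0] / view.pixel_pitch
        v = local[:, 1] / view.pixel_pitch
        half_u = view.detector_size[0] / 2.0 / view.pixel_pitch
        half_v = view.detector_size[1] / 2.0 / view.pixel_pitch
        vis = ok & (np.abs(u) <= half_u) & (np.abs(v) <= half_v)
        if pixel_noise_sd > 0:
            u = u + rng.normal(0.0, pixel_noise_sd, size=u.shape)
            v = v + rng.normal(0.0, pixel_noise_sd, size=v.shape)
        uv[i, vis, 0] = u[vis]
        uv[i, vis, 1] = v[vis]
        visible[i] = vis
    return uv, visible


# ---------------------------------------------------------------------------
# model-based tracking emulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialConfig:
    """Noise and motion settings for one simulated trial."""

    motion: str = "hop"
    mean_speed_mps: float = 0.9
    speed_sd_mps: float = 0.3
    duration_s: float = 0.3
    seed: int = 0
    bead_pixel_noise_sd: float = 0.5       # px
    model_rot_noise_sd: float = 0.5        # deg, per bone
    model_trans_noise_sd: float = 0.4      # mm per axis, per bone
    outlier_frame_prob: float = 0.05
    outlier_noise_multiplier: float = 4.0
    noise_correlation_hz: float | None = 4.0

    def __post_init__(self) -> None:
        if self.motion not in ("hop", "drop"):
            raise ValueError("motion must be 'hop' or 'drop'")
        for name in ("bead_pixel_noise_sd", "model_rot_noise_sd", "model_trans_noise_sd",
                     "speed_sd_mps", "outlier_noise_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.outlier_frame_prob <= 1.0:
            raise ValueError("outlier_frame_prob must be in [0, 1]")


def _ar1_series(rng, n, frame_rate_hz, corner_hz):
    """Stationary unit-variance AR(1) series; ``corner_hz=None`` gives white noise."""
    if corner_hz is None or corner_hz <= 0:
        return rng.standard_normal(n)
    phi = float(np.exp(-2.0 * np.pi * corner_hz / frame_rate_hz))
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi * phi)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + innov[k - 1]
    return x


def emulate_model_based(
    truth,
    cfg: TrialConfig,
    partial_out_of_view=None,
    rng: np.random.Generator | None = None,
    frame_rate_hz: float = 250.0,
    rotation_center=(0.0, 0.0, 0.0),
):
    """Emulate intensity-based 2D-3D model registration as a noise process.

    Each truth pose is perturbed in the bone's own (CT) frame by a rotation
    about ``rotation_center`` — axis smoothly wandering on the sphere, angle
    with a half-normal ``|N(0, model_rot_noise_sd)|`` marginal — plus a
    per-axis Gaussian translation.  Noise is temporally correlated (AR(1)
    with corner ``noise_correlation_hz``), as registration error tracks the
    slowly-varying pose of the bone against the detectors; set the corner to
    ``None`` for frame-independent noise.  Frames partially out of the field
    of view, or drawn as outliers with probability ``outlier_frame_prob``,
    receive noise scaled by ``outlier_noise_multiplier``.

    Returns ``(transforms, outlier_flags)``.
    """
    truth = list(truth)
    n = len(truth)
    if n == 0:
        raise ValueError("truth sequence is empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if partial_out_of_view is None:
        partial_out_of_view = np.zeros(n, dtype=bool)
    partial_out_of_view = np.asarray(partial_out_of_view, bool)

    corner = cfg.noise_correlation_hz
    angle = np.abs(_ar1_series(rng, n, frame_rate_hz, corner)) * np.radians(cfg.model_rot_noise_sd)
    axes = np.stack([_ar1_series(rng, n, frame_rate_hz, corner) for _ in range(3)], axis=1)
    axes /= np.maximum(np.linalg.norm(axes, axis=1, keepdims=True), 1e-300)
    trans = np.stack([_ar1_series(rng, n, frame_rate_hz, corner) for _ in range(3)], axis=1)
    trans *= cfg.model_trans_noise_sd
    drawn = rng.random(n) < cfg.outlier_frame_prob
    flagged = drawn | partial_out_of_view
    mult = np.where(flagged, cfg.outlier_noise_multiplier, 1.0)

    c = np.asarray(rotation_center, float)
    rotvecs = (angle * mult)[:, None] * axes
    rmats = Rotation.from_rotvec(rotvecs).as_matrix()                   # (n, 3, 3)
    # perturbation rotates about c then translates: p' = R (p - c) + c + t
    pert_t = c[None, :] - np.einsum("nij,j->ni", rmats, c) + trans * mult[:, None]
    truth_r = np.stack([t.rotation for t in truth])
    truth_t = np.stack([t.translation for t in truth])
    out_r = np.einsum("nij,njk->nik", truth_r, rmats)
    out_t = np.einsum("nij,nj->ni", truth_r, pert_t) + truth_t
    out = [RigidTransform(out_r[k], out_t[k]) for k in range(n)]
    return out, flagged


# ---------------------------------------------------------------------------
# volume subtraction & bead masking demos
# ---------------------------------------------------------------------------

def soft_tissue_volume(total_mask, bone_masks, voxel_size_mm) -> float:
    """Soft-tissue volume (cm^3): total specimen minus the union of bone masks."""
    total = np.asarray(total_mask, bool)
    union = np.zeros_like(total)
    for m in bone_masks:
        m = np.asarray(m, bool)
        if m.shape != total.shape:
            raise ValueError("bone mask shape differs from total mask")
        if np.any(m & ~total):
            raise ValueError("bone voxels found outside the total specimen mask")
        union |= m
    vs = np.asarray(voxel_size_mm, float)
    voxel_mm3 = float(vs.prod()) if vs.ndim else float(vs) ** 3
    return (int(total.sum()) - int(union.sum())) * voxel_mm3 / 1000.0


def mask_beads(image, bead_centers, radius: float):
    """Inpaint bead silhouettes so they cannot act as fiducial markers.

    Pixels within ``radius`` of each centre are replaced by the median
    intensity of the surrounding annulus (radius .. 2*radius], leaving the
    local background level in place of the bead.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    img = np.array(image, dtype=float)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy in np.atleast_2d(np.asarray(bead_centers, float)):
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"bead centre ({cx}, {cy}) outside image bounds")
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        disk = d2 <= radius**2
        annulus = (d2 > radius**2) & (d2 <= (2.0 * radius) ** 2)
        if not annulus.any():
            raise ValueError("annulus around bead centre is empty")
        img[disk] = np.median(img[annulus])
    return img


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

@dataclass
class TrackedTrial:
    """All per-frame products of one simulated trial.

    ``marker`` sequences may contain ``None`` where too few beads were
    visible for a rigid fit; ``truth`` and ``model`` are always complete.
    """

    specimen_id: int
    trial_id: str
    motion: str
    frames: np.ndarray
    truth: dict = field(default_factory=dict)       # bone -> list[RigidTransform]
    marker: dict = field(default_factory=dict)      # bone -> list[RigidTransform | None]
    model: dict = field(default_factory=dict)       # bone -> list[RigidTransform]
    fully_in_fov: dict = field(default_factory=dict)    # bone -> (n,) bool
    outlier_flags: dict = field(default_factory=dict)   # bone -> (n,) bool
    observations: pd.DataFrame | None = None
    speed_setpoint_mps: float = float("nan")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        n = self.n_frames
        for d in (self.truth, self.marker, self.model):
            for bone, seq in d.items():
                if len(seq) != n:
                    raise ValueError(f"{bone}: sequence length {len(seq)} != {n} frames")


def simulate_trial(
    specimen: SpecimenConfig,
    geometry: BVRGeometry,
    cfg: TrialConfig,
    trial_id: str = "trial",
    with_observations: bool = True,
) -> TrackedTrial:
    """Simulate the physical scene of one trial: trajectory + bead views.

    Generates the femur trajectory, locks the tibia to it through the frozen
    relative pose, and projects every bead into both views with pixel noise,
    recording per-bone field-of-view flags.  Model-based tracking is added
    by :func:`emulate_trial_model`, marker-based poses by
    :func:`bvrkin.markers.track_trial`.  ``with_observations=False`` skips
    the bead projection entirely (useful for pure trajectory/velocity
    studies); field-of-view flags then default to all-true.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    speed = abs(float(rng.normal(cfg.mean_speed_mps, cfg.speed_sd_mps)))
    traj_seed = int(rng.integers(0, 2**31 - 1))
    femur_truth = generate_trajectory(
        cfg.motion, speed, cfg.duration_s, geometry.frame_rate_hz, traj_seed
    )
    tibia_truth = [t @ specimen.frozen_relative_pose for t in femur_truth]
    n = len(femur_truth)

    trial = TrackedTrial(
        specimen_id=specimen.specimen_id,
        trial_id=trial_id,
        motion=cfg.motion,
        frames=np.arange(n),
        speed_setpoint_mps=speed,
    )
    trial.truth = {"femur": femur_truth, "tibia": tibia_truth}

    if not with_observations:
        trial.fully_in_fov = {b: np.ones(n, dtype=bool) for b in ("femur", "tibia")}
        return trial

    obs_rows = []
    for bone_name in ("femur", "tibia"):
        bone = getattr(specimen, bone_name)
        truth_seq = trial.truth[bone_name]
        fully = np.zeros(n, dtype=bool)
        for k, pose in enumerate(truth_seq):
            world = pose.apply(bone.beads.coordinates)
            uv, visible = project_beads(geometry, world, cfg.bead_pixel_noise_sd, rng)
            fully[k] = bool(visible.all())
            for vi in range(2):
                for bi, label in enumerate(bone.beads.labels):
                    obs_rows.append(
                        (k, vi + 1, label, uv[vi, bi, 0], uv[vi, bi, 1], bool(visible[vi, bi]))
                    )
        trial.fully_in_fov[bone_name] = fully

    trial.observations = pd.DataFrame(
        obs_rows, columns=["frame", "view", "bead_label", "u", "v", "visible"]
    )
    return trial


def emulate_trial_model(
    trial: TrackedTrial,
    specimen: SpecimenConfig,
    cfg: TrialConfig,
    frame_rate_hz: float = 250.0,
) -> TrackedTrial:
    """Fill ``trial.model`` by emulating 2D-3D registration for both bones.

    Noise magnitudes are scaled by the specimen's ``noise_scale``; frames
    where a bone is partially outside the field of view get the outlier
    noise multiplier.  The noise stream is seeded independently of the
    scene simulation so the stage can be rerun in isolation.
    """
    from .kinematics import build_anatomical_frame

    rot_sd = cfg.model_rot_noise_sd * specimen.noise_scale
    trans_sd = cfg.model_trans_noise_sd * specimen.noise_scale
    bone_cfg = dataclasses.replace(cfg, model_rot_noise_sd=rot_sd, model_trans_noise_sd=trans_sd)
    for idx, bone_name in enumerate(("femur", "tibia")):
        bone = getattr(specimen, bone_name)
        truth_seq = trial.truth[bone_name]
        fully = trial.fully_in_fov.get(bone_name)
        if fully is None:
            raise ValueError(f"trial has no field-of-view flags for {bone_name}")
        # perturbation pivots on the bone's anatomical origin so rotational
        # registration error does not pick up a spurious lever arm from the
        # arbitrary CT origin
        acs = build_anatomical_frame(bone)
        center_ct = acs.transform.inverse().apply(np.zeros(3))
        rng = np.random.default_rng([cfg.seed, 2, idx])
        model_seq, flags = emulate_model_based(
            truth_seq,
            bone_cfg,
            partial_out_of_view=~np.asarray(fully, bool),
            rng=rng,
            frame_rate_hz=frame_rate_hz,
            rotation_center=center_ct,
        )
        trial.model[bone_name] = model_seq
        trial.outlier_flags[bone_name] = flags
    trial.validate()
    return trial
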