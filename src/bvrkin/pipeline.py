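"""Reproducible simulate → track → kinematics → agreement pipeline.

Each stage reads and writes only documented CSV/JSON formats under the
output directory, so stages can be rerun independently:

* ``simulate``: geometry + specimens + per-trial truth transforms, 2D bead
  observations, and field-of-view flags.
* ``track-markers``: marker-based (gold standard) transform CSVs.
* ``emulate-model``: model-based transform CSVs with outlier flags.
* ``kinematics``: per-trial 6-DOF kinematics CSVs per method (optionally
  time-normalized copies).
* ``agreement``: stratified accuracy/bias/precision report (CSV + JSON) and
  optional Bland–Altman plots.

Rerunning with the same config and seeds reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import agreement, io, markers, scene
from .kinematics import build_anatomical_frame, filter_pose_sequence, kinematics_table, time_normalize
from .transforms import RigidTransform

log = logging.getLogger("bvrkin")

STAGES = ["simulate", "track-markers", "emulate-model", "kinematics", "agreement"]

__all__ = [
    "PipelineConfig",
    "GeometrySettings",
    "SpecimenSettings",
    "TrialSettings",
    "RunManifest",
    "default_demo_config",
    "load_config",
    "run_pipeline",
    "make_fixtures",
    "STAGES",
]


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class GeometrySettings(BaseModel):
    sid_mm: float = 1850.0
    separation_deg: float = 55.0
    frame_rate_hz: float = 250.0
    detector_size_mm: tuple[float, float] = (450.0, 450.0)
    pixel_pitch_mm: float = 0.45
    source_to_iso_mm: float = 1400.0

    def build(self) -> scene.BVRGeometry:
        return scene.build_geometry(
            self.sid_mm, self.separation_deg, self.frame_rate_hz,
            self.detector_size_mm, self.pixel_pitch_mm, self.source_to_iso_mm,
        )


class SpecimenSettings(BaseModel):
    specimen_id: int
    seed: int
    soft_tissue_volume_cm3: float | None = None
    noise_scale: float = 1.0

    def build(self) -> scene.SpecimenConfig:
        return scene.generate_specimen(
            self.seed, self.soft_tissue_volume_cm3, self.specimen_id, self.noise_scale
        )


class TrialSettings(BaseModel):
    trial_id: str
    specimen_id: int
    motion: str
    seed: int
    mean_speed_mps: float
    speed_sd_mps: float
    duration_s: float
    bead_pixel_noise_sd: float = 0.5
    model_rot_noise_sd: float = 0.5
    model_trans_noise_sd: float = 0.4
    outlier_frame_prob: float = 0.05
    outlier_noise_multiplier: float = 4.0
    noise_correlation_hz: float | None = 4.0

    def build(self) -> scene.TrialConfig:
        return scene.TrialConfig(
            motion=self.motion,
            mean_speed_mps=self.mean_speed_mps,
            speed_sd_mps=self.speed_sd_mps,
            duration_s=self.duration_s,
            seed=self.seed,
            bead_pixel_noise_sd=self.bead_pixel_noise_sd,
            model_rot_noise_sd=self.model_rot_noise_sd,
            model_trans_noise_sd=self.model_trans_noise_sd,
            outlier_frame_prob=self.outlier_frame_prob,
            outlier_noise_multiplier=self.outlier_noise_multiplier,
            noise_correlation_hz=self.noise_correlation_hz,
        )


class PipelineConfig(BaseModel):
    geometry: GeometrySettings = Field(default_factory=GeometrySettings)
    specimens: list[SpecimenSettings]
    trials: list[TrialSettings]
    normalize_frames: dict[str, int] = {"hop": 75, "drop": 10}
    min_beads: int = 3
    filter_cutoff_hz: float = 10.0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# Speed set-points: hop 0.9 ± 0.3 m/s (horizontal), drop 1.8 ± 0.4 m/s
# (vertical near free-fall), matching the validation study conditions.
MOTION_SPEEDS = {"hop": (0.9, 0.3), "drop": (1.8, 0.4)}
# Hop trials are long (~75 frames at 250 Hz), drop trials short (~10 frames).
MOTION_DURATIONS = {"hop": 0.3, "drop": 0.04}


def default_demo_config(seed: int = 0) -> PipelineConfig:
    """Three-specimen demo: 33 trials mirroring the cadaver study layout.

    18 hop + 15 drop trials split across the three specimen presets, with
    specimen 2 contributing two imaging sessions' worth (the study repeated
    one specimen's collection).
    """
    specimens = [
        SpecimenSettings(specimen_id=sid, seed=seed * 1000 + sid,
                         soft_tissue_volume_cm3=scene.SPECIMEN_SOFT_TISSUE_CM3[sid])
        for sid in (1, 2, 3)
    ]
    plan = {1: (4, 3), 2: (10, 8), 3: (4, 4)}   # specimen -> (n_hop, n_drop)
    trials = []
    k = 0
    for sid, (n_hop, n_drop) in plan.items():
        for motion, count in (("hop", n_hop), ("drop", n_drop)):
            for j in range(count):
                mean, sd = MOTION_SPEEDS[motion]
                trials.append(
                    TrialSettings(
                        trial_id=f"s{sid}_{motion}{j + 1}",
                        specimen_id=sid,
                        motion=motion,
                        seed=seed * 100000 + k,
                        mean_speed_mps=mean,
                        speed_sd_mps=sd,
                        duration_s=MOTION_DURATIONS[motion],
                    )
                )
                k += 1
    return PipelineConfig(specimens=specimens, trials=trials)


def load_config(path) -> PipelineConfig:
    with Path(path).open() as fh:
        return PipelineConfig.model_validate(json.load(fh))


def save_config(cfg: PipelineConfig, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(cfg.model_dump(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# specimen (de)serialization
# ---------------------------------------------------------------------------

def _specimen_to_dict(s: scene.SpecimenConfig) -> dict:
    def bone(b):
        return {
            "name": b.name,
            "bead_labels": list(b.beads.labels),
            "bead_coordinates": b.beads.coordinates.tolist(),
            "landmarks": {k: np.asarray(v).tolist() for k, v in b.landmarks.items()},
            "bead_diameter_mm": b.bead_diameter_mm,
        }

    return {
        "specimen_id": s.specimen_id,
        "femur": bone(s.femur),
        "tibia": bone(s.tibia),
        "frozen_relative_pose": s.frozen_relative_pose.as_matrix().tolist(),
        "flexion_deg": s.flexion_deg,
        "soft_tissue_volume_cm3": s.soft_tissue_volume_cm3,
        "noise_scale": s.noise_scale,
    }


def _specimen_from_dict(d: dict) -> scene.SpecimenConfig:
    from .transforms import PointSet

    def bone(bd):
        return scene.BoneModel(
            bd["name"],
            PointSet(tuple(bd["bead_labels"]), np.array(bd["bead_coordinates"]), "CT"),
            {k: np.array(v) for k, v in bd["landmarks"].items()},
            bd["bead_diameter_mm"],
        )

    return scene.SpecimenConfig(
        specimen_id=d["specimen_id"],
        femur=bone(d["femur"]),
        tibia=bone(d["tibia"]),
        frozen_relative_pose=RigidTransform.from_matrix(np.array(d["frozen_relative_pose"])),
        flexion_deg=d["flexion_deg"],
        soft_tissue_volume_cm3=d["soft_tissue_volume_cm3"],
        noise_scale=d["noise_scale"],
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _trial_dir(out: Path, trial_id: str) -> Path:
    d = out / "trials" / trial_id
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_sparse_transforms(path, seq, frames) -> None:
    """Write only the frames that have a pose (marker tracking may drop some)."""
    keep = [(f, t) for f, t in zip(frames, seq) if t is not None]
    io.write_transform_csv(path, [t for _, t in keep], [f for f, _ in keep])


def _read_sparse_transforms(path, n_frames: int):
    frames, ts = io.read_transform_csv(path)
    seq = [None] * n_frames
    for f, t in zip(frames, ts):
        seq[f] = t
    return seq


def stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    geometry = cfg.geometry.build()
    specimens = {s.specimen_id: s.build() for s in cfg.specimens}
    written = []
    gpath = out / "geometry.json"
    with gpath.open("w") as fh:
        json.dump(cfg.geometry.model_dump(), fh, indent=1)
    spath = out / "specimens.json"
    with spath.open("w") as fh:
        json.dump({str(k): _specimen_to_dict(v) for k, v in specimens.items()}, fh)
    written += [gpath, spath]

    meta_rows = []
    for ts in cfg.trials:
        trial = scene.simulate_trial(specimens[ts.specimen_id], geometry, ts.build(), ts.trial_id)
        d = _trial_dir(out, ts.trial_id)
        for bone in ("femur", "tibia"):
            p = d / f"truth_{bone}.csv"
            io.write_transform_csv(p, trial.truth[bone], trial.frames)
            written.append(p)
        p = d / "observations.csv"
        io.write_observation_csv(
            p, trial.observations.itertuples(index=False, name=None)
        )
        written.append(p)
        flags = pd.DataFrame(
            {
                "frame": trial.frames,
                "fully_in_fov_femur": trial.fully_in_fov["femur"].astype(int),
                "fully_in_fov_tibia": trial.fully_in_fov["tibia"].astype(int),
            }
        )
        p = d / "fov_flags.csv"
        flags.to_csv(p, index=False)
        written.append(p)
        meta_rows.append(
            {
                "trial_id": ts.trial_id,
                "specimen_id": ts.specimen_id,
                "motion": ts.motion,
                "seed": ts.seed,
                "n_frames": trial.n_frames,
                "speed_setpoint_mps": trial.speed_setpoint_mps,
            }
        )
        log.info("simulate %s: %d frames, speed %.2f m/s",
                 ts.trial_id, trial.n_frames, trial.speed_setpoint_mps)
    p = out / "trials.csv"
    pd.DataFrame(meta_rows).to_csv(p, index=False, float_format="%.17g")
    written.append(p)
    return written


def _load_scene(cfg: PipelineConfig, out: Path):
    gpath = out / "geometry.json"
    spath = out / "specimens.json"
    if not gpath.exists() or not spath.exists():
        raise FileNotFoundError(
            "simulate stage outputs not found; run the 'simulate' stage first"
        )
    geometry = GeometrySettings.model_validate(json.loads(gpath.read_text())).build()
    specimens = {
        int(k): _specimen_from_dict(v) for k, v in json.loads(spath.read_text()).items()
    }
    return geometry, specimens


def _load_trial_skeleton(cfg: PipelineConfig, out: Path, ts: TrialSettings) -> scene.TrackedTrial:
    d = out / "trials" / ts.trial_id
    if not d.exists():
        raise FileNotFoundError(f"missing simulate output for trial {ts.trial_id}")
    truth = {}
    for bone in ("femur", "tibia"):
        frames, seq = io.read_transform_csv(d / f"truth_{bone}.csv")
        truth[bone] = seq
    flags = pd.read_csv(d / "fov_flags.csv")
    trial = scene.TrackedTrial(
        specimen_id=ts.specimen_id,
        trial_id=ts.trial_id,
        motion=ts.motion,
        frames=np.array(frames),
    )
    trial.truth = truth
    trial.fully_in_fov = {
        bone: flags[f"fully_in_fov_{bone}"].to_numpy(bool) for bone in ("femur", "tibia")
    }
    trial.observations = io.read_observation_csv(d / "observations.csv")
    return trial


def stage_track_markers(cfg: PipelineConfig, out: Path) -> list[Path]:
    geometry, specimens = _load_scene(cfg, out)
    written = []
    for ts in cfg.trials:
        trial = _load_trial_skeleton(cfg, out, ts)
        spec = specimens[ts.specimen_id]
        markers.track_trial(
            trial, {"femur": spec.femur, "tibia": spec.tibia}, geometry, cfg.min_beads
        )
        d = out / "trials" / ts.trial_id
        n_ok = {}
        for bone in ("femur", "tibia"):
            p = d / f"marker_{bone}.csv"
            _write_sparse_transforms(p, trial.marker[bone], trial.frames)
            written.append(p)
            n_ok[bone] = sum(t is not None for t in trial.marker[bone])
        log.info("track-markers %s: trackable femur %d/%d, tibia %d/%d",
                 ts.trial_id, n_ok["femur"], trial.n_frames, n_ok["tibia"], trial.n_frames)
    return written


def stage_emulate_model(cfg: PipelineConfig, out: Path) -> list[Path]:
    geometry, specimens = _load_scene(cfg, out)
    written = []
    for ts in cfg.trials:
        trial = _load_trial_skeleton(cfg, out, ts)
        scene.emulate_trial_model(
            trial, specimens[ts.specimen_id], ts.build(), geometry.frame_rate_hz
        )
        d = out / "trials" / ts.trial_id
        for bone in ("femur", "tibia"):
            p = d / f"model_{bone}.csv"
            io.write_transform_csv(p, trial.model[bone], trial.frames)
            written.append(p)
        p = d / "model_outlier_flags.csv"
        pd.DataFrame(
            {
                "frame": trial.frames,
                "outlier_femur": trial.outlier_flags["femur"].astype(int),
                "outlier_tibia": trial.outlier_flags["tibia"].astype(int),
            }
        ).to_csv(p, index=False)
        written.append(p)
        log.info("emulate-model %s: %d outlier-noise frames",
                 ts.trial_id, int(trial.outlier_flags["femur"].sum()))
    return written


def _load_full_trial(cfg: PipelineConfig, out: Path, ts: TrialSettings) -> scene.TrackedTrial:
    trial = _load_trial_skeleton(cfg, out, ts)
    d = out / "trials" / ts.trial_id
    for bone in ("femur", "tibia"):
        mpath = d / f"marker_{bone}.csv"
        if not mpath.exists():
            raise FileNotFoundError(
                f"{mpath} missing; run the 'track-markers' stage first"
            )
        trial.marker[bone] = _read_sparse_transforms(mpath, trial.n_frames)
        mo = d / f"model_{bone}.csv"
        if not mo.exists():
            raise FileNotFoundError(f"{mo} missing; run the 'emulate-model' stage first")
        _, trial.model[bone] = io.read_transform_csv(mo)
    return trial


def stage_kinematics(cfg: PipelineConfig, out: Path, normalize: bool = True) -> list[Path]:
    geometry, specimens = _load_scene(cfg, out)
    written = []
    kdir = out / "kinematics"
    kdir.mkdir(exist_ok=True)
    for ts in cfg.trials:
        trial = _load_full_trial(cfg, out, ts)
        spec = specimens[ts.specimen_id]
        run = agreement.common_frame_run(trial)
        if len(run) < 7:
            log.warning("kinematics %s: only %d usable frames; skipped", ts.trial_id, len(run))
            continue
        acs_f = build_anatomical_frame(spec.femur)
        acs_t = build_anatomical_frame(spec.tibia)
        for method, store in (("marker", trial.marker), ("model", trial.model)):
            femur = filter_pose_sequence(
                [store["femur"][k] for k in run], geometry.frame_rate_hz, cfg.filter_cutoff_hz
            )
            tibia = filter_pose_sequence(
                [store["tibia"][k] for k in run], geometry.frame_rate_hz, cfg.filter_cutoff_hz
            )
            table = kinematics_table(
                femur, tibia, acs_f, acs_t, geometry.frame_rate_hz, frames=run,
                method=method, specimen=ts.specimen_id, trial=ts.trial_id, motion=ts.motion,
            )
            p = kdir / f"{ts.trial_id}_{method}.csv"
            table.to_csv(p, index=False, float_format="%.17g")
            written.append(p)
            if normalize and ts.motion in cfg.normalize_frames:
                norm = time_normalize(table, cfg.normalize_frames[ts.motion])
                p = kdir / f"{ts.trial_id}_{method}_norm.csv"
                norm.to_csv(p, index=False, float_format="%.17g")
                written.append(p)
        log.info("kinematics %s: %d analyzed frames", ts.trial_id, len(run))
    return written


def stage_agreement(cfg: PipelineConfig, out: Path, plots: bool = False) -> list[Path]:
    geometry, specimens = _load_scene(cfg, out)
    trials = [_load_full_trial(cfg, out, ts) for ts in cfg.trials]
    joint, bones = agreement.compute_differences(
        trials, specimens, geometry.frame_rate_hz, cfg.filter_cutoff_hz
    )
    report = agreement.summarize_differences(joint, bones)
    written = []
    p = out / "report.csv"
    report.to_csv(p, index=False, float_format="%.17g")
    written.append(p)
    p = out / "report.json"
    with p.open("w") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=1)
    written.append(p)
    if plots:
        p = out / "bland_altman.png"
        agreement.bland_altman_plot(joint, p)
        written.append(p)
    pooled_n = int(report.loc[report["analysis"] == "pooled", "n"].iloc[0])
    log.info("agreement: pooled n = %d frames", pooled_n)
    return written


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seeds: list = field(default_factory=list)
    stages_run: list = field(default_factory=list)
    files: dict = field(default_factory=dict)       # stage -> [paths]
    counts: dict = field(default_factory=dict)

    def validate_outputs(self) -> None:
        for stage, paths in self.files.items():
            for p in paths:
                p = Path(p)
                if not p.exists() or p.stat().st_size == 0:
                    raise RuntimeError(f"stage {stage}: output {p} missing or empty")

    def save(self, path, base=None) -> None:
        def rel(p):
            p = Path(p)
            return str(p.relative_to(base)) if base is not None else str(p)

        with Path(path).open("w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seeds": self.seeds,
                    "stages_run": self.stages_run,
                    "files": {k: [rel(p) for p in v] for k, v in self.files.items()},
                    "counts": self.counts,
                },
                fh,
                indent=1,
            )


def run_pipeline(
    config: PipelineConfig,
    out,
    stages: list | None = None,
    normalize: bool = True,
    plots: bool = False,
) -> RunManifest:
    """Run the requested stages (default: all, in order) and write a manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    stages.sort(key=STAGES.index)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seeds=[t.seed for t in config.trials],
    )
    save_config(config, out / "config.json")
    runners = {
        "simulate": lambda: stage_simulate(config, out),
        "track-markers": lambda: stage_track_markers(config, out),
        "emulate-model": lambda: stage_emulate_model(config, out),
        "kinematics": lambda: stage_kinematics(config, out, normalize),
        "agreement": lambda: stage_agreement(config, out, plots),
    }
    for stage in stages:
        log.info("=== stage %s ===", stage)
        manifest.files[stage] = runners[stage]()
        manifest.stages_run.append(stage)

    manifest.counts["trials"] = len(config.trials)
    if "simulate" in stages:
        meta = pd.read_csv(out / "trials.csv")
        manifest.counts["frames_generated"] = int(meta["n_frames"].sum())
    if "agreement" in stages:
        report = pd.read_csv(out / "report.csv")
        manifest.counts["frames_analyzed"] = int(
            report.loc[report["analysis"] == "pooled", "n"].iloc[0]
        )
        manifest.counts["dofs"] = int(report["dof"].nunique())
        manifest.counts["stratifications"] = int(report["analysis"].nunique())
    manifest.validate_outputs()
    manifest.save(out / "manifest.json", base=out)
    return manifest


def make_fixtures(seed: int, out) -> RunManifest:
    """Generate the miniature 2-trial (1 hop, 1 drop) fixture dataset.

    Small enough to commit as plain text and regenerate bit-identically:
    the hop trial is shortened to 12 frames.
    """
    specimens = [
        SpecimenSettings(specimen_id=1, seed=seed * 1000 + 1,
                         soft_tissue_volume_cm3=scene.SPECIMEN_SOFT_TISSUE_CM3[1])
    ]
    trials = []
    for j, motion in enumerate(("hop", "drop")):
        mean, sd = MOTION_SPEEDS[motion]
        trials.append(
            TrialSettings(
                trial_id=f"mini_{motion}",
                specimen_id=1,
                motion=motion,
                seed=seed * 100 + j,
                mean_speed_mps=mean,
                speed_sd_mps=sd,
                duration_s=0.048 if motion == "hop" else 0.04,
            )
        )
    cfg = PipelineConfig(specimens=specimens, trials=trials)
    return run_pipeline(cfg, out, normalize=False)
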