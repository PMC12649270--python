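"""From tracked poses to filtered 6-DOF tibiofemoral kinematics.

Quaternion + translation components are low-pass filtered (zero-phase
2nd-order Butterworth, 10 Hz cutoff at 250 Hz), the tibia is expressed in
the femoral anatomical frame, and the pose is decomposed X-Y-Z into
FE/AA/IE rotations (deg) and ML/AP/IS translations (mm).
"""

from bvrkin import TrialConfig, build_anatomical_frame, build_geometry, generate_specimen, simulate_trial
from bvrkin.kinematics import filter_pose_sequence, kinematics_table

geometry = build_geometry()
specimen = generate_specimen(seed=7)
cfg = TrialConfig(motion="drop", mean_speed_mps=1.8, speed_sd_mps=0.4, duration_s=0.04, seed=3)
trial = simulate_trial(specimen, geometry, cfg, with_observations=False)

acs_f = build_anatomical_frame(specimen.femur)
acs_t = build_anatomical_frame(specimen.tibia)
femur = filter_pose_sequence(trial.truth["femur"], geometry.frame_rate_hz)
tibia = filter_pose_sequence(trial.truth["tibia"], geometry.frame_rate_hz)
table = kinematics_table(femur, tibia, acs_f, acs_t, geometry.frame_rate_hz, motion="drop")

print(table[["frame", "FE", "AA", "IE", "ML", "AP", "IS", "speed"]].round(3).to_string(index=False))
print(f"\nspecimen flexion set at freezing: {specimen.flexion_deg:.1f} deg")
print("Because the specimen is frozen, every row repeats the same joint pose")
print("(FE matches the freezing flexion) while the speed column tracks the")
print("~1.8 m/s vertical drop — any row-to-row kinematic change would be")
print("tracking error, which is the premise the validation rests on.")
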