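{
 "filter_cutoff_hz": 10.0,
 "geometry": {
  "detector_size_mm": [
   450.0,
   450.0
  ],
  "frame_rate_hz": 250.0,
  "pixel_pitch_mm": 0.45,
  "separation_deg": 55.0,
  "sid_mm": 1850.0,
  "source_to_iso_mm": 1400.0
 },
 "min_beads": 3,
 "normalize_frames": {
  "drop": 10,
  "hop": 75
 },
 "specimens": [
  {
   "noise_scale": 1.0,
   "seed": 3001,
   "soft_tissue_volume_cm3": 3038.0,
   "specimen_id": 1
  }
 ],
 "trials": [
  {
   "bead_pixel_noise_sd": 0.5,
   "duration_s": 0.048,
   "mean_speed_mps": 0.9,
   "model_rot_noise_sd": 0.5,
   "model_trans_noise_sd": 0.4,
   "motion": "hop",
   "noise_correlation_hz": 4.0,
   "outlier_frame_prob": 0.05,
   "outlier_noise_multiplier": 4.0,
   "seed": 300,
   "specimen_id": 1,
   "speed_sd_mps": 0.3,
   "trial_id": "mini_hop"
  },
  {
   "bead_pixel_noise_sd": 0.5,
   "duration_s": 0.04,
   "mean_speed_mps": 1.8,
   "model_rot_noise_sd": 0.5,
   "model_trans_noise_sd": 0.4,
   "motion": "drop",
   "noise_correlation_hz": 4.0,
   "outlier_frame_prob": 0.05,
   "outlier_noise_multiplier": 4.0,
   "seed": 301,
   "specimen_id": 1,
   "speed_sd_mps": 0.4,
   "trial_id": "mini_drop"
  }
 ]
}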