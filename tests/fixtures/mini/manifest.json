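{
 "config_hash": "fb2f679baf19ebb6",
 "seeds": [
  300,
  301
 ],
 "stages_run": [
  "simulate",
  "track-markers",
  "emulate-model",
  "kinematics",
  "agreement"
 ],
 "files": {
  "simulate": [
   "geometry.json",
   "specimens.json",
   "trials/mini_hop/truth_femur.csv",
   "trials/mini_hop/truth_tibia.csv",
   "trials/mini_hop/observations.csv",
   "trials/mini_hop/fov_flags.csv",
   "trials/mini_drop/truth_femur.csv",
   "trials/mini_drop/truth_tibia.csv",
   "trials/mini_drop/observations.csv",
   "trials/mini_drop/fov_flags.csv",
   "trials.csv"
  ],
  "track-markers": [
   "trials/mini_hop/marker_femur.csv",
   "trials/mini_hop/marker_tibia.csv",
   "trials/mini_drop/marker_femur.csv",
   "trials/mini_drop/marker_tibia.csv"
  ],
  "emulate-model": [
   "trials/mini_hop/model_femur.csv",
   "trials/mini_hop/model_tibia.csv",
   "trials/mini_hop/model_outlier_flags.csv",
   "trials/mini_drop/model_femur.csv",
   "trials/mini_drop/model_tibia.csv",
   "trials/mini_drop/model_outlier_flags.csv"
  ],
  "kinematics": [
   "kinematics/mini_hop_marker.csv",
   "kinematics/mini_hop_model.csv",
   "kinematics/mini_drop_marker.csv",
   "kinematics/mini_drop_model.csv"
  ],
  "agreement": [
   "report.csv",
   "report.json"
  ]
 },
 "counts": {
  "trials": 2,
  "frames_generated": 22,
  "frames_analyzed": 22,
  "dofs": 6,
  "stratifications": 4
 }
}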