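{
 "sid_mm": 1850.0,
 "separation_deg": 55.0,
 "frame_rate_hz": 250.0,
 "detector_size_mm": [
  450.0,
  450.0
 ],
 "pixel_pitch_mm": 0.45,
 "source_to_iso_mm": 1400.0
}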