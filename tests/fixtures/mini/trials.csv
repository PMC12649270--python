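trial_id,specimen_id,motion,seed,n_frames,speed_setpoint_mps
mini_hop,1,hop,300,12,0.5308781579834827
mini_drop,1,drop,301,10,2.3949240736358473
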