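frame,fully_in_fov_femur,fully_in_fov_tibia
0,1,1
1,1,1
2,1,1
3,1,1
4,1,1
5,1,1
6,1,1
7,1,1
8,1,1
9,1,1
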