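frame,outlier_femur,outlier_tibia
0,0,0
1,0,0
2,0,1
3,0,0
4,0,0
5,0,0
6,0,0
7,1,0
8,0,0
9,0,1
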