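frame,FE,AA,IE,ML,AP,IS,speed,method,specimen,trial,motion
0,25.05089875623306,1.641733890194325,0.83287749562245428,-1.0276313445283218,-1.0261358878643136,-40.195258299790062,2.4022640693892696,marker,1,mini_drop,drop
1,25.124648043642466,1.6293346176979635,0.90669504931891931,-1.0310163094011067,-1.0067381019188453,-40.20401724965167,2.4019120517176114,marker,1,mini_drop,drop
2,25.193632926856655,1.6170200819747618,0.9734729744129661,-1.0326810153902422,-0.98459350464499096,-40.209916100846243,2.4008746715045932,marker,1,mini_drop,drop
3,25.252856167126161,1.604865447262892,1.0275966062390265,-1.0310729032149872,-0.95755052268215124,-40.210500615363536,2.3992176772976932,marker,1,mini_drop,drop
4,25.297881838283857,1.592989146576024,1.0655046696084041,-1.0249459922650459,-0.92383605612080899,-40.204164392263799,2.3970752976636009,marker,1,mini_drop,drop
5,25.325737679109118,1.5811982009193128,1.0854857209969067,-1.0136024891639455,-0.88165084382490555,-40.190346041728112,2.3946555484384811,marker,1,mini_drop,drop
6,25.335614899394425,1.5689952168906589,1.0873695878865517,-0.99682812547886002,-0.82930476656711782,-40.169268819574391,2.3922173604207071,marker,1,mini_drop,drop
7,25.329243121514828,1.5559000530439122,1.072921846881645,-0.97475184705190188,-0.76573869100291247,-40.141652510034689,2.3900503219253215,marker,1,mini_drop,drop
8,25.310456861931566,1.541722828499799,1.0461058253536117,-0.94818851319649333,-0.69183194083658783,-40.108783064092819,2.3884984591854606,marker,1,mini_drop,drop
9,25.284737812353292,1.5267605692075144,1.0126195367282926,-0.91899256786757988,-0.61157667861928289,-40.072926177020229,2.3879244465726694,marker,1,mini_drop,drop
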