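frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.98408273233024723,-0.0070227961354908837,0.17757211567099745,-1.8155237896734917,0.10116928487510059,0.84363289991454982,-0.52730285982500336,3.1736679688143976,-0.14610253840127324,0.53687448301833629,0.83091506049445163,-13.08257136720249,0,0,0,1
1,0.98338031390841485,-0.011061686871710193,0.1812203004658676,0.54789090821370934,0.10567734552847187,0.84650900568263432,-0.52178041544336862,3.4527772853425063,-0.14763284478544433,0.53225946903906796,0.83360926144015868,-13.163556444302117,0,0,0,1
2,0.98286365304476297,-0.010878411630615557,0.18401277043699488,2.7039140295809077,0.10733633287444978,0.84533735337487659,-0.52333896342067399,3.3505467782656559,-0.1498597716819581,0.53412210134907823,0.83201900800515149,-13.463427196880367,0,0,0,1
3,0.98374844596141364,-0.01209109820620273,0.17914463545602444,4.6335937339785609,0.10602376201360343,0.84433063984760814,-0.52522826704492165,3.1916264320620709,-0.14490671812233791,0.53568607967605086,0.83189089854638787,-13.472532663642049,0,0,0,1
4,0.98382526844014306,-0.0090165518311679255,0.17890372542727048,6.7982839296293562,0.10248256954428964,0.84746843136200034,-0.52085946356424195,3.2040274164866904,-0.14691890320268558,0.53076921504351215,0.83468489637935461,-13.58064595348521,0,0,0,1
5,0.98427714985726755,-0.010999164927203077,0.17628814662295714,8.8360488887226118,0.10353538786109517,0.84454515948081466,-0.5253797646064966,2.6644375321060974,-0.14310456222394063,0.53537135893548671,0.83240530530641432,-13.800354007307135,0,0,0,1
6,0.98430938668526025,-0.010376719899212473,0.17614583437430328,10.988162682821521,0.10198572307156832,0.84809340302545655,-0.51993893106236078,2.7781711538805336,-0.14399285945093129,0.52974513063249007,0.83584457466583495,-13.74482472788744,0,0,0,1
7,0.98377396934561379,-0.016899089937172308,0.17861466344415872,13.201882269220324,0.10944331530172328,0.84539613962057925,-0.52280735252135546,2.3815358149658721,-0.14216517848524748,0.53387244532183598,0.83352820837230268,-13.846294170199421,0,0,0,1
8,0.98423481544377167,-0.013157472121977836,0.17637661124912052,15.319400032794512,0.10439496451235585,0.84820363484686068,-0.51928054577177885,2.4553039651336981,-0.14277086345899823,0.52950682220338974,0.83620512183748319,-14.06192355854683,0,0,0,1
9,0.9841689516954838,-0.010224800101534787,0.17693763867955409,17.559570081287102,0.10220540055835517,0.84835666433891732,-0.51946609722719306,2.2701978371055347,-0.14479478794251868,0.52932638658452413,0.83597131879631592,-14.169040854440823,0,0,0,1
10,0.98422590793470299,-0.010579147492791836,0.17659967097487805,19.72156465555048,0.10233712284658386,0.84830268750231319,-0.51952830881852352,2.0267025025552368,-0.14431380889434159,0.52940592366791461,0.83600412232699517,-14.234611139066473,0,0,0,1
11,0.98483787642999465,-0.012879843992975424,0.17299845885896145,21.571441378633409,0.10138420787406434,0.85194185104292219,-0.51372787040933254,2.3346286302583561,-0.14076789244216073,0.52347797667168006,0.84033041620371951,-14.180502183963561,0,0,0,1
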