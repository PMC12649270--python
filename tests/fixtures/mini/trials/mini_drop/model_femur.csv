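frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.9981060073480027,0.0036376588856304602,0.061409816264668605,-0.90914574867612263,-0.0011861910455312826,0.99920260825674145,-0.039909154385031648,-1.6065915838430631,-0.061506024474290849,0.039760722965718101,0.99731444081724363,42.933092674165067,0,0,0,1
1,0.99821510015009152,0.0031667777024566679,0.059637113874885704,-1.1067480694861269,-0.00071534972221463944,0.99915550939289277,-0.041082311578144182,-1.610415034282251,-0.059716849440654432,0.04096632237353038,0.99737438222769204,33.346510151072373,0,0,0,1
2,0.99840928144305296,0.00039959956902536068,0.056380378222842531,-1.1294013646906844,0.0020378115949473818,0.99906577358806226,-0.043167434123303983,-1.4493571978061839,-0.056344955872463333,0.043213659473258288,0.99747572681377017,23.651665299301278,0,0,0,1
3,0.99842536039901919,0.0039476306279724385,0.055957268737077931,-1.2239626590028654,-0.0015149100592963382,0.99905443098905999,-0.043450534733620573,-1.607429198765868,-0.056075883939539536,0.043297345571644684,0.99748726062383819,13.704245252369606,0,0,0,1
4,0.99845758962619657,0.0056267612670045826,0.055233877968959261,-1.1664109672346756,-0.0031628562691419118,0.99900013915405339,-0.044595048047992247,-1.5451594139976894,-0.055429577466064944,0.044351567366059615,0.99747706761313948,4.2109878484305368,0,0,0,1
5,0.99852259528808351,0.0068468704241548689,0.053904981815638603,-1.00412357771747,-0.0043814239752711093,0.99894455195640852,-0.045722918110711379,-1.2092279471085619,-0.05416114680375974,0.045419186276338466,0.99749870561063714,-5.3443410509389828,0,0,0,1
6,0.99867800893175362,0.0068785984578365296,0.050940350993728116,-0.81262439375535234,-0.004520025361230205,0.9989186524423801,-0.046271969629932491,-1.3060329806973185,-0.051203553068534254,0.045980546820969928,0.99762918234542541,-14.527155800700047,0,0,0,1
7,0.99932282979480236,0.0063529365645708961,0.036242544721846501,0.36017957552990354,-0.004740475749901751,0.99900238521461582,-0.04440452933173681,-1.8708450537931167,-0.036488487781396198,0.044202653003128901,0.99835600650615208,-24.665189984727995,0,0,0,1
8,0.99863266883084001,0.004483571116104563,0.052083493871288085,-0.81290320338070787,-0.0020556830241475,0.99891264935124935,-0.046575671045858004,-1.336848944243104,-0.052235686183852346,0.046404919524922969,0.99755602175155433,-33.587046396267112,0,0,0,1
9,0.99887756780236636,0.0051772594442625235,0.047082911187349433,-0.87734107139994844,-0.0030134627246041759,0.99894091808569252,-0.045912538772337752,-1.3337719651383153,-0.047270747652607116,0.045719122462715645,0.99783527611405021,-43.558660278942561,0,0,0,1
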