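frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.99838918406459443,0.051601126485225544,0.023587303540017916,-11.409902726354128,-0.051624415441119585,0.99866649889840797,0.00037908885353358314,3.3800933435321099,-0.023536288432883339,-0.0015961589682533253,0.99972170897872992,-1.1430235959755706,0,0,0,1
1,0.99868096377767146,0.045575040815833884,0.023648430026904071,-9.4251292980871355,-0.045771065631078717,0.99892138712773804,0.0078148505930624272,2.9591643008550594,-0.023266760391119776,-0.0088869563648915576,0.99968979181917805,-1.4433424662705008,0,0,0,1
2,0.99900463630907665,0.038510743085585046,0.022509093717103603,-7.4910669885304682,-0.038767555825648441,0.99918675407639512,0.011086347170371344,2.5118751356697633,-0.022063844820758318,-0.011947934770195727,0.99968516724339396,-1.6727530750308475,0,0,0,1
3,0.9988489993481362,0.041905943135504019,0.023335990040078729,-5.331417436271245,-0.042137069849635278,0.99906665365431802,0.0095020471714992241,2.5476004582269152,-0.022916017230612266,-0.010474420551340001,0.99968252093772225,-1.6530426861063887,0,0,0,1
4,0.99865058733723178,0.045632122815018897,0.024793422079206137,-3.2538790469692298,-0.046038063205205995,0.99881063969334372,0.016056237781203953,2.3084597914584073,-0.024031253552739926,-0.017176012423381248,0.99956364652277885,-1.8334637606109894,0,0,0,1
5,0.99882853030013041,0.043551991703693491,0.021090070581242754,-1.0351542290028064,-0.04379233986766478,0.99897930480667985,0.011071564337429406,2.3383289273584662,-0.020586355369403203,-0.011982177874004723,0.99971627444290445,-1.8942676944485513,0,0,0,1
6,0.99879029870913438,0.045008148826817126,0.019804185004743648,1.1562344944950809,-0.045398813089050194,0.99877389294478425,0.019739770566711272,1.9719684859537079,-0.018891452422312688,-0.0206149778341869,0.99960899141327864,-2.2133319115744214,0,0,0,1
7,0.99874782221903668,0.043854657373964899,0.024073982623215036,3.0180566518979557,-0.044096684693955002,0.99898098688547687,0.0096161447743091742,2.5609363989734053,-0.023627738184867471,-0.010665686472547703,0.99966393008867538,-2.0052053823268565,0,0,0,1
8,0.99867689680590754,0.047090247079168285,0.020663117290124457,5.3123847651895915,-0.047415379646161625,0.99875440883314337,0.015537458266023383,2.1232101441863858,-0.01990571674501888,-0.016496650156347901,0.99966575562759252,-2.2641077227044448,0,0,0,1
9,0.99881466654680662,0.044699473908015964,0.019267042412833689,7.5173646839506318,-0.04493650689750759,0.99891716610257897,0.012050129187771203,2.1906863493121467,-0.018707544970989008,-0.012901639350808245,0.99974175438621071,-2.2799309517686623,0,0,0,1
10,0.9987010785683792,0.047892776086430167,0.0173907350359758,9.7920696763761352,-0.048254358620596211,0.99861421674090811,0.021003880523793535,1.5807952797113121,-0.01636070109962745,-0.021815776898335845,0.99962813052547261,-2.5120676013702905,0,0,0,1
11,0.99888194428097576,0.043722300761324814,0.017978370493252894,11.688549222290192,-0.044112437980301775,0.99878631501942927,0.02190866826950269,1.1346514289881817,-0.016998653031650861,-0.022677242911018119,0.99959831354852913,-2.6639844251578566,0,0,0,1
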