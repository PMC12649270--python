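frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.9834168336107163,-0.010540602299273907,0.18105310567411356,-1.7396813906551767,0.10593729353752529,0.84367588161348106,-0.52629677618398929,3.3816023379821711,-0.14720265353932108,0.53674938517606563,0.83080170696989963,-13.105595124159255,0,0,0,1
1,0.98351595208231202,-0.010706002867897855,0.18050416477803505,0.39053722676566949,0.10564486962355657,0.84417190426222344,-0.52555966129119314,3.3122646917147018,-0.14674990126690102,0.53596564960534965,0.83138756841876749,-13.235928201531808,0,0,0,1
2,0.98361435336966063,-0.010873788137473842,0.1799571187164479,2.5207459696603305,0.10535572367807593,0.84466962351714103,-0.52481749074862227,3.2287054667583637,-0.14629755751021034,0.53517752927318674,0.83197478136515313,-13.362471167109495,0,0,0,1
3,0.98371198213631972,-0.011043765713805394,0.17941229456280763,4.6509403262061797,0.10507014878756284,0.84516802936324498,-0.52407181375839029,3.1313151320607666,-0.14584580911082942,0.53438659917807452,0.8325622875098897,-13.484875788355682,0,0,0,1
4,0.98380878384290338,-0.011215745472867068,0.17887001953104203,6.7811158061678345,0.10478843594030185,0.84566611459381125,-0.52332418854949969,3.0205558861999124,-0.14539484353556956,0.53359444307572668,0.83314903216169722,-13.602804940317094,0,0,0,1
5,0.98390470476711211,-0.011389539698843754,0.17833062082152509,8.9112679432347939,0.10451087350638678,0.84616287690188752,-0.52257617920457611,2.8969593337837347,-0.1449448490153207,0.53280265027359774,0.83373396632580388,-13.715933512242314,0,0,0,1
6,0.98399969202270454,-0.01156496320850723,0.1777944254615671,11.041392297311056,0.10423774672526916,0.84665732092610557,-0.52182935245142004,2.7611238022938611,-0.14449601467466672,0.53201281239103215,0.83431604874587151,-13.82394928169343,0,0,0,1
7,0.98409369357742993,-0.011741833461947024,0.17726176014043107,13.171484456757019,0.10396933720188556,0.84714846024649593,-0.52108527442616537,2.6137113131358483,-0.14404853065176487,0.53122652009189386,0.83489424789498035,-13.926553753816968,0,0,0,1
8,0.98418665826993768,-0.011919970659737175,0.17673295103891695,15.301540040583895,0.10370592241237453,0.84763531932638758,-0.5203455074150749,2.4554442224498167,-0.14360258820805344,0.53044535979676943,0.83546754391180555,-14.023462963536584,0,0,0,1
9,0.9842785358256797,-0.012099197826685519,0.17620832365358599,17.431554700601168,0.10344777522036952,0.84811693539688082,-0.5196116065822235,2.2871015489467315,-0.14315837982742083,0.52967091038205427,0.83603493047852639,-14.114408238532553,0,0,0,1
10,0.98436927687181974,-0.012279340882376394,0.17568820261572859,19.561524123517685,0.10319516340482615,0.84859236028078744,-0.51888511669051895,2.1095150076576989,-0.1427160993045358,0.52890473987342612,0.83659541663740999,-14.199136920981092,0,0,0,1
11,0.98445883295116154,-0.01246022869878001,0.17517291150520684,21.691444032996884,0.10294834920031309,0.84906066215334441,-0.51816756882369119,1.9235647700081513,-0.14227594182210607,0.52814840214138525,0.83714802854341985,-14.277413046140019,0,0,0,1
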