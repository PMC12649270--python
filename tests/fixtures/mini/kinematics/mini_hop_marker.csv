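frame,FE,AA,IE,ML,AP,IS,speed,method,specimen,trial,motion
0,24.884188306751795,1.6164390552208516,1.191260628733775,-1.307376648683773,-1.8548555878674513,-40.284999559556994,0.54327307050808005,marker,1,mini_hop,hop
1,24.981355724235137,1.6080472352167192,1.1717244870243464,-1.2439596700953217,-1.6513684550686492,-40.27039921681164,0.54280256513021286,marker,1,mini_hop,hop
2,25.072096718119308,1.5988884508993997,1.1543603180858599,-1.1861173855473517,-1.4603629641892475,-40.2560155192011,0.54155462034242041,marker,1,mini_hop,hop
3,25.150879882542775,1.5887322476824417,1.1404070668462352,-1.1385643651958564,-1.2896274557762002,-40.242173689763852,0.53988290461957222,marker,1,mini_hop,hop
4,25.213932739786124,1.5777204280865982,1.1296610247800833,-1.1042038443022726,-1.1405960866946376,-40.22824172736096,0.53807363768507099,marker,1,mini_hop,hop
5,25.25958807745474,1.5658532949754171,1.1207848555793198,-1.0843785827675774,-1.0087146909100291,-40.213189204274514,0.53622271052869463,marker,1,mini_hop,hop
6,25.28820833536739,1.5526856222213485,1.1118149513363385,-1.0796075196268529,-0.88503476223520394,-40.196108323199347,0.53429585681358016,marker,1,mini_hop,hop
7,25.302018985819235,1.5374609182183168,1.1004782254895067,-1.0903202214657828,-0.75840380982181799,-40.176319017782347,0.532264838044747,marker,1,mini_hop,hop
8,25.304462053296469,1.519288950224422,1.0850255124856971,-1.1165158649220608,-0.61855159897667811,-40.153179336481934,0.53021679834072299,marker,1,mini_hop,hop
9,25.299016985041813,1.4973127833218083,1.0651946592342825,-1.1565939376294008,-0.45958288467813624,-40.126199105903446,0.52837433404318268,marker,1,mini_hop,hop
10,25.288444890024312,1.47130081960736,1.042040301369495,-1.2070006820320902,-0.28213978111476834,-40.095525589954406,0.52705283822508986,marker,1,mini_hop,hop
11,25.275157613435692,1.4425397567541074,1.0171280517688837,-1.2628675775348857,-0.093404415699874122,-40.06227551540573,0.52656587282568279,marker,1,mini_hop,hop
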