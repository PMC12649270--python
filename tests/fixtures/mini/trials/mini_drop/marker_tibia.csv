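frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.97191137234709146,-0.025818075510541019,0.23392672202919693,8.4770681730791502,0.1555305250631106,0.81644413085218193,-0.55608383987544441,0.35803935433757061,-0.17663108468213176,0.5768469538568769,0.79752683450154582,30.95401734726688,0,0,0,1
1,0.97252784971015771,-0.022597691204339496,0.2316871293153113,8.3066058062192845,0.15174925181917434,0.81628211468993472,-0.55736493772899698,0.37993424548120203,-0.17652689911301689,0.57721127292314844,0.79728627248936224,21.44736633458627,0,0,0,1
2,0.9725658141627963,-0.023890323777468116,0.23139790308398697,8.3835251698554245,0.15368028206149201,0.81272848151601929,-0.56200959621537261,0.20828515706119433,-0.17463707517981045,0.58215261552489261,0.79410340901558185,11.689101233815087,0,0,0,1
3,0.97406626585658584,-0.027282104624086548,0.22461210227298092,7.9901575257559294,0.15200903245987432,0.81421170194332393,-0.56031469592468208,0.43931853260662379,-0.1675952379121213,0.5799267119092173,0.79724327845604492,2.3912598231228515,0,0,0,1
4,0.97300242853889007,-0.028165319249476725,0.22906983400045583,8.3183494234228625,0.15624866451378128,0.81086816515344218,-0.56398508276225645,0.30668023389899446,-0.16986061608001185,0.5845507108303476,0.79337748743750869,-7.4048488307214413,0,0,0,1
5,0.97412311102256033,-0.027259979290593345,0.2243681307601515,8.1017135743480715,0.15305920104395077,0.80999184539684477,-0.5661149100371774,0.33998780832503783,-0.16630407555894589,0.58580722419554587,0.79320416699157215,-16.815677405664623,0,0,0,1
6,0.97423813635223355,-0.026883242359534234,0.22391369979785619,8.1333967412653791,0.15236305696583702,0.81046935606267756,-0.56561906063654954,0.31619118445484773,-0.16626951779851584,0.58516383531758553,0.79368616800815051,-26.435347176093529,0,0,0,1
7,0.97453821872230706,-0.027046923743424271,0.2225841956778839,8.0717287587456106,0.15191654473219851,0.80977210778127673,-0.56673670861882519,0.65183088439304981,-0.16491398875226754,0.58612080442131242,0.79326274268890951,-35.919440353157015,0,0,0,1
8,0.97465906682995052,-0.026889102228824475,0.22207359056740225,8.1788688777397667,0.1521647216009622,0.80737720561765969,-0.57007713982330688,0.57357954147155255,-0.16396829250276457,0.58942261920488614,0.79100908656182956,-45.685032786193013,0,0,0,1
9,0.97534428455587097,-0.023304942504399916,0.21945479315581856,8.2314074375145339,0.14659955161990587,0.81172187430032172,-0.56534606237880081,1.0124093099504883,-0.16496089854580365,0.58357902501481229,0.79512478486947036,-54.96739333413872,0,0,0,1
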