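frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.99827573959519433,-0.0011221644046733473,0.05868806081918132,-1.0957190077878458,0.0036692799991748046,0.99905489227334099,-0.043311183417116178,-1.1950227243985942,-0.058583992011083608,0.043451846586219277,0.99733637901577255,43.153241152473385,0,0,0,1
1,0.99817520937578297,0.0059349881481993759,0.060091823930493928,-0.99800331491986682,-0.0033622789805758065,0.99907697817846697,-0.042823904000459295,-1.2490633915918288,-0.060290517228412742,0.042543713865440841,0.99727382696171596,33.50073642862985,0,0,0,1
2,0.99817100863738761,0.0090785918978751358,0.059768023933985399,-1.2993003214825194,-0.0062760482586689207,0.99887930145515347,-0.046912176913029451,-0.94750085253676986,-0.060126938505768501,0.046451267944119114,0.9971093375213711,24.10292951169815,0,0,0,1
3,0.99840135010298114,0.0040584237086427324,0.056376176790788469,-1.1333409632580569,-0.0019979228152993246,0.99932955281227009,-0.036557532472133038,-1.5648781030145038,-0.056486745498118447,0.036386454526761376,0.99774008314290052,14.267037896364847,0,0,0,1
4,0.99842957566112844,0.0035063732451237621,0.055911428096627108,-1.3217821647260806,-0.00082065214908882468,0.99884766816532133,-0.047986063922246823,-0.87962372631901431,-0.05601525662878476,0.047864821605910372,0.99728193098914897,4.8174567623635056,0,0,0,1
5,0.99852132768322022,0.003421900544437988,0.054253559868485367,-1.3961278726673925,-0.0011755769854081049,0.99914270088749257,-0.041382137233334691,-1.3711699392037922,-0.05434865389768849,0.041257167376240876,0.99766931894270372,-4.9690795172675948,0,0,0,1
6,0.99836070242508312,0.013597997117572884,0.055596783429316884,-1.3466206966281433,-0.011334084484023975,0.99910163041768563,-0.040834674305442513,-1.228053551680155,-0.056102106753711821,0.040137595482453152,0.99761792638599012,-14.524841124976049,0,0,0,1
7,0.99868560326599065,0.0041370685692115492,0.051087674569288269,-1.3915442319035023,-0.0013612522831185395,0.99852645338753232,-0.054250058779124227,-0.44508083852190694,-0.051236830712540912,0.054109209465398447,0.99721962507241324,-23.869793571795881,0,0,0,1
8,0.99863395759246232,0.0096898918803435628,0.051345153019184284,-1.3570967090829491,-0.0074625616758110871,0.99903011884768345,-0.0433950666368733,-1.0468401102377811,-0.05171584782685977,0.042952620764410074,0.99773771275471834,-33.671305755070151,0,0,0,1
9,0.99866130049583857,0.0097806428342742582,0.050793168021970869,-1.5451455405287007,-0.0073408969296789367,0.99882039409903001,-0.047999287121019224,-0.84490032521667757,-0.051202715984873685,0.047562163087969109,0.99755507242365571,-43.097333276799631,0,0,0,1
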