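frame,FE,AA,IE,ML,AP,IS,speed,method,specimen,trial,motion
0,25.413274030169418,1.4285096323492221,1.2872985480539907,-1.3707082470861174,-0.16837385551651707,-39.755620625758255,2.3802131629621734,model,1,mini_drop,drop
1,25.399815413725435,1.4319229245488714,1.2552774270912637,-1.4453727204452314,0.016311991019893668,-39.642594332701549,2.3792360592359656,model,1,mini_drop,drop
2,25.387404563281024,1.4394736959153076,1.2266223940752112,-1.5047257837028916,0.19723372570555497,-39.521571647572344,2.3762700548983844,model,1,mini_drop,drop
3,25.377227725416152,1.4537126828688274,1.2038487723856379,-1.5372892250740691,0.37543525353137852,-39.385120222314228,2.3712727018696569,model,1,mini_drop,drop
4,25.37043366040993,1.474859739223082,1.1882242973686201,-1.5362346305346666,0.55924586772268725,-39.22637626105633,2.364406673154265,model,1,mini_drop,drop
5,25.36781264570995,1.501446187268489,1.1799378006026406,-1.4971193082459102,0.76037615973896955,-39.038690415590082,2.3562321582996266,model,1,mini_drop,drop
6,25.36949509061137,1.531144242824982,1.1786165996008675,-1.4154951725000089,0.98769560272847556,-38.816397737296732,2.3476764573911644,model,1,mini_drop,drop
7,25.374873230180093,1.5612823785945236,1.1836195474367379,-1.2888086579049389,1.24409960728293,-38.557276910959743,2.3399361143856248,model,1,mini_drop,drop
8,25.382831232405877,1.5900712046829606,1.1937016440902632,-1.1219879999285922,1.526031188421026,-38.265727519506576,2.3344067144234892,model,1,mini_drop,drop
9,25.392091199874706,1.6175757550796319,1.2066445292068371,-0.93084790212485835,1.8233708941860609,-37.954877632434503,2.3323789424612933,model,1,mini_drop,drop
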