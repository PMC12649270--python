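frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.97288061776069001,-0.026969762653358032,0.22973013622073937,8.3042001746618297,0.1547215017159487,0.81415977413711038,-0.55964731669487278,0.64024486071938491,-0.17194348051711533,0.58001421885970261,0.79625306619706626,31.523472152177423,0,0,0,1
1,0.97348269270260857,-0.026419404336370446,0.22722997619810106,7.9963689112378944,0.15290898900465402,0.81395285672843132,-0.56044588329757627,0.76557078168678228,-0.17014784186128482,0.58032987351861987,0.79640878310815388,21.966367853703407,0,0,0,1
2,0.97547553514598506,-0.029028197336304382,0.2181853434377721,6.8849615916429254,0.14989580153776533,0.81348769946259658,-0.56193328029616008,3.1180361418895481,-0.16117918293937605,0.58085723425163305,0.7978885538748749,13.094659200007344,0,0,0,1
3,0.97405600225907618,-0.026858725195918916,0.22470761745859127,8.0606200917110193,0.15189868322198724,0.81362554223416317,-0.56119539116032513,1.1333268980339435,-0.16775486430650183,0.58076853040175491,0.79659664799476382,2.8267968835301942,0,0,0,1
4,0.97422565777890857,-0.026373113212435139,0.22402862902927603,8.4164307711127453,0.15127611978362865,0.81309622599485321,-0.56212993413990697,0.89913891956471148,-0.16733171638533484,0.5815315865646602,0.79612882784077554,-6.7215404420527003,0,0,0,1
5,0.9746803845663381,-0.027267004321606267,0.22193390551454883,8.296363139653673,0.15093061580134143,0.81254362800976965,-0.56302113796424125,1.2824247222252503,-0.16497908096314229,0.58226228029647142,0.79608576157880806,-16.131745520349401,0,0,0,1
6,0.97532641182367374,-0.029328553803288984,0.21881093741165147,8.0588524427756045,0.15082966792280278,0.81227701224592941,-0.56343275255448511,1.324534904511685,-0.16121042668963784,0.58253402588057812,0.79665883979148266,-25.695651116983569,0,0,0,1
7,0.97471160842937055,-0.030291250419213604,0.22140397589264257,8.0868461237526503,0.15324736162790739,0.81170463549845939,-0.56360520833682759,1.4844701771501063,-0.16264232704654319,0.58328211429663612,0.79581998504343432,-35.047224151605057,0,0,0,1
8,0.97458416279794557,-0.030229766124053772,0.22197268044404181,8.2019791510111375,0.15372628926988044,0.81099359563762596,-0.56449766679949021,1.3802109330660364,-0.16295378980171255,0.58427352248312625,0.79502862421073861,-44.777466818163191,0,0,0,1
9,0.97490575726896778,-0.031936623253544447,0.22031526624131667,9.4097039498971071,0.15411980864867475,0.81096520540465311,-0.56443114744411915,2.7883727413368433,-0.16064199023268155,0.58422212190069467,0.79553671395852843,-53.062990913348258,0,0,0,1
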