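frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.99848289859144701,0.050992857025917659,0.020775701017219525,-11.094639851753636,-0.051016082532220432,0.99869765809193123,0.00058910504830434265,2.7688598358652907,-0.020718603801613868,-0.0016481061939649811,0.99978398827070902,-2.0044803313719406,0,0,0,1
1,0.99869566111852293,0.046588464963518997,0.020892376489518472,-9.0249855264024408,-0.046664010438930814,0.99890569755417957,0.0031428527731258643,2.562498367624666,-0.020723093224520716,-0.0041136755026560815,0.9997767906293219,-2.2278280825225458,0,0,0,1
2,0.99868852016902232,0.045006788039946316,0.024405505791432875,-7.003604795492345,-0.045241216583686988,0.99893428077535429,0.0091397491132635105,2.5518355695378467,-0.023968145623644806,-0.01023189728998591,0.99966036045909656,-2.1787595108653792,0,0,0,1
3,0.99873636067928728,0.044324870741619705,0.023685178716471945,-4.8611565494678146,-0.044501369298106497,0.99898495817824795,0.0069772103449542936,2.4053096354517622,-0.02335187332284187,-0.008022416552566896,0.99969511894625707,-2.3473774390254301,0,0,0,1
4,0.99877935401019069,0.04368854528917257,0.023045889297261913,-2.4319714722425569,-0.043883452045964416,0.99900446344587834,0.008020265066824149,2.6881859531830496,-0.022672552558441136,-0.0090218083402661218,0.99970223683592696,-2.5046407659131589,0,0,0,1
5,0.99878253105961579,0.044134093464780061,0.022037183218144542,-0.52998318987485493,-0.044336410779578637,0.99897809349327971,0.0087778926694627082,2.7510339792816665,-0.021627258941726259,-0.0097442554653601014,0.99971861598956602,-2.34898866024312,0,0,0,1
6,0.99874255469959683,0.044508915859442805,0.023070887307169073,1.4881464790121564,-0.044759260977870675,0.99894313922830724,0.010450509337333125,2.5259367886569244,-0.022581363750622301,-0.011470004259452703,0.99967920905330931,-2.3979025471458546,0,0,0,1
7,0.99871914941857254,0.044483297008607946,0.024110098960550906,3.6635662348690845,-0.044794915092999738,0.99891746666124837,0.012542343516470893,2.4901538262645859,-0.02352607418279834,-0.013606288484307054,0.99963062815583414,-2.5268461961834716,0,0,0,1
8,0.99860005952042652,0.046334863398503491,0.025514732207938831,5.7342830100140372,-0.046683341852544871,0.99882204740007896,0.013235679846265849,2.5177336764255709,-0.024871403645135147,-0.01440826364821373,0.99958682225175643,-2.8454601925816121,0,0,0,1
9,0.99848151989192824,0.048717563023995915,0.025714849548610773,7.6609660523165752,-0.049113179323458017,0.99868082058489993,0.014983798337299441,2.1262977124520388,-0.02495095290858762,-0.016223983754737558,0.99955701803352837,-2.9009392483692764,0,0,0,1
10,0.99837445940446912,0.048536721102294081,0.029876839081006468,9.6837510911071245,-0.049008731746245225,0.99868155589392216,0.015273969029672041,1.800458137483768,-0.029096099763693616,-0.016713366564906205,0.99943688162715316,-2.9747223856894118,0,0,0,1
11,0.99854592706072931,0.047999218976461498,0.024537859076899451,11.758242362897555,-0.048425848299450083,0.9986804237350998,0.017098200629296085,2.1307552784915806,-0.023684779224361061,-0.018261605239702026,0.9995526724526137,-3.2235102553818002,0,0,0,1
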