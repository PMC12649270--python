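frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.97227050982412699,-0.025356819014261029,0.23248029476884724,8.3587981125110105,0.15474983923160424,0.81508796948878937,-0.55828674465048445,0.19844962869923255,-0.17533551546713158,0.5787820260893739,0.79640995931225966,30.995151964465258,0,0,0,1
1,0.97258758948979018,-0.025294157800199512,0.23115705992164254,8.3230923636992884,0.15410640811831594,0.81453633495829791,-0.5592689639248497,0.26765852777008536,-0.1741395869620411,0.57956083771583666,0.79610592237390621,21.427191978862012,0,0,0,1
2,0.97290449264941214,-0.025276819017235587,0.22982151901630041,8.2907587033635082,0.15349092937122716,0.81397905254573766,-0.56024872745727849,0.33951654884456839,-0.17290859661493629,0.58034402248762151,0.79580363958676426,11.859597228329822,0,0,0,1
3,0.97322048306261266,-0.025304375579167697,0.22847665071933171,8.26188274411364,0.15290451416337694,0.81341670324456772,-0.56122497844554342,0.41390610654861071,-0.17164527635748306,0.58113075590549101,0.79550295011701655,2.292342338974608,0,0,0,1
4,0.97353482934578639,-0.025376304725296648,0.22712547019028778,8.2365412118708825,0.1523482323665018,0.81284987153731048,-0.56219667593875045,0.49070540701455845,-0.17035243510285608,0.58192020887770068,0.79520369613971276,-7.2745989520054088,0,0,0,1
5,0.97384680727645512,-0.025491989925984098,0.2257710220711871,8.2148017492501921,0.15182311079847863,0.81227914456625105,-0.56316279558418325,0.56978865240355869,-0.16903295236411101,0.58271154935553926,0.79490572476410037,-16.841253748225377,0,0,0,1
6,0.97415570201729007,-0.02565072301739629,0.22441637336853559,8.1967227418773412,0.15133013149515542,0.81170511133502754,-0.56412233029215386,0.65102625119516955,-0.16768977168825808,0.58350394398090888,0.79460888985076472,-26.407649943056459,0,0,0,1
7,0.97446081024766784,-0.025851706559891715,0.22306460624536567,8.1823531680230346,0.15087023000912897,0.81112836194344018,-0.56507429082196303,0.73428503390060595,-0.16632589392049357,0.58429655973563044,0.79431305370908789,-35.973816165615503,0,0,0,1
8,0.97476144219157557,-0.026094056413759361,0.22171881074116268,8.1717324718820041,0.15044429373829463,0.81054948685744965,-0.56601770629257797,0.81942847385500006,-0.16494437031370815,0.58508856558216971,0.79401808866474444,-45.539781723829748,0,0,0,1
9,0.9750569235317359,-0.026376804525272524,0.22038207743794064,8.1648904607701667,0.15005316028725268,0.80996907621596481,-0.56695162462212323,0.90631691274359683,-0.16354829549902053,0.58587913408559988,0.79372387848827708,-55.105576544623567,0,0,0,1
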