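analysis,stratum,dof,n,mad,mad_sd,bias,loa,loa_ci,outlier_frac
pooled,all,FE,22,0.13156047195189788,0.077971393444156323,-0.01069222783021379,0.30422411503877161,0.11234219973597132,0.045454545454545456
pooled,all,AA,22,0.12379230190701702,0.079742722366922508,-0.031169367331165085,0.28669234781025876,0.10586816563299056,0.045454545454545456
pooled,all,IE,22,0.26443657699924394,0.16136452773559037,0.26443657699924394,0.31627447436175715,0.11679208982368028,0.045454545454545456
pooled,all,ML,22,0.42617089470279751,0.25158395111185144,-0.14539311622721438,0.94287812281470695,0.34818082184717003,0.090909090909090912
pooled,all,AP,22,1.0355338270289765,0.72564802990421895,0.42715459132973271,2.3673108909742706,0.87418748154490655,0
pooled,all,IS,22,0.89179120209034157,0.48652495564412834,0.89179120209034157,0.95358891306249149,0.35213604327067011,0.045454545454545456
bone,femur,FE,22,0.13726562247714499,0.077176868921026487,0.041222602630516678,0.30310453608352989,,0
bone,femur,AA,22,0.14525186936525436,0.098178766838818515,0.030326940028961677,0.34385756401684203,,0.045454545454545456
bone,femur,IE,22,0.10746590989003522,0.090831462685723702,-0.032352574877008232,0.27195798905025503,,0.090909090909090912
bone,femur,ML,22,0.46099792628604203,0.14823593012478076,0.46099792628604203,0.29054242304457029,,0
bone,femur,AP,22,0.4202200178604461,0.19577712732919827,-0.11827020402229178,0.89533267940565897,,0.045454545454545456
bone,femur,IS,22,0.4002898364372538,0.21424029354258217,-0.4002898364372538,0.41991097534346106,,0
bone,tibia,FE,22,0.086581199338081255,0.06823303458556855,0.031095697601567159,0.21015030666905074,,0.045454545454545456
bone,tibia,AA,22,0.11734669555582539,0.069499651740790244,-0.017994073940437207,0.26957638986287702,,0
bone,tibia,IE,22,0.22311228180367326,0.097211915637689342,0.22311228180367326,0.19053535464987112,,0.045454545454545456
bone,tibia,ML,22,0.37586719237741234,0.30618852944304503,0.29280519863949722,0.76399155632744831,,0
bone,tibia,AP,22,0.77396657691954185,0.73793131772553311,0.50878649152830879,1.860350104602321,,0.045454545454545456
bone,tibia,IS,22,0.32726089111732309,0.24235136355647455,0.30452944944043581,0.5323829408679156,,0.045454545454545456
specimen,1,FE,22,0.13156047195189788,0.077971393444156323,-0.01069222783021379,0.30422411503877161,,0.045454545454545456
specimen,1,AA,22,0.12379230190701702,0.079742722366922508,-0.031169367331165085,0.28669234781025876,,0.045454545454545456
specimen,1,IE,22,0.26443657699924394,0.16136452773559037,0.26443657699924394,0.31627447436175715,,0.045454545454545456
specimen,1,ML,22,0.42617089470279751,0.25158395111185144,-0.14539311622721438,0.94287812281470695,,0.090909090909090912
specimen,1,AP,22,1.0355338270289765,0.72564802990421895,0.42715459132973271,2.3673108909742706,,0
specimen,1,IS,22,0.89179120209034157,0.48652495564412834,0.89179120209034157,0.95358891306249149,,0.045454545454545456
motion,drop,FE,10,0.13295506853385247,0.11070731834703353,0.13295506853385247,0.21698634396018571,,0.10000000000000001
motion,drop,AA,10,0.11196133841230471,0.071347346610389856,-0.083052160891126617,0.20885299252571232,,0
motion,drop,IE,10,0.1993142246863292,0.12013304844549029,0.1993142246863292,0.23546077495316095,,0.10000000000000001
motion,drop,ML,10,0.36488785399888002,0.16210693915260788,-0.36488785399888002,0.31772960073911144,,0.10000000000000001
motion,drop,AP,10,1.6000383428902374,0.52061271963030742,1.6000383428902374,1.0204009304754025,,0
motion,drop,IS,10,1.1542579965175208,0.56236628267884814,1.1542579965175208,1.1022379140505423,,0
motion,hop,FE,12,0.13039830813360234,0.039691598143021735,-0.13039830813360234,0.077795532360322606,,0
motion,hop,AA,12,0.13365143815261063,0.087985946492979236,0.012066293968802858,0.32247381953678567,,0
motion,hop,IE,12,0.31870520392667284,0.17559534290468115,0.31870520392667284,0.34416687209317504,,0.083333333333333329
motion,hop,ML,12,0.47724009528939543,0.30508171280127916,0.037519165249173682,1.1428709130266346,,0
motion,hop,AP,12,0.56511339714459241,0.50238791968545771,-0.55024853497068804,1.0193518299327153,,0
motion,hop,IS,12,0.67306887340102561,0.2798657132744185,0.67306887340102561,0.54853679801786026,,0
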