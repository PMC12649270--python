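frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.99810341907032196,0.0036869801568828503,0.061448930157130169,-1.1117081795284656,-0.0012344809778055657,0.99920285744822868,-0.039901450149213848,-1.3858673304409443,-0.061547062455072105,0.039749916284408875,0.99731233987078183,43.108633325445254,0,0,0,1
1,0.99816750771898433,0.0044825366873760663,0.060345119097716518,-1.1617339761467553,-0.0020119827986899456,0.99915961861638936,-0.04093908220233039,-1.3206790735539589,-0.060477917120954475,0.040742648308593254,0.99733768511448184,33.528937030901865,0,0,0,1
2,0.99823196958916305,0.0052465804360077549,0.059206488528442638,-1.2087582663732297,-0.0027612616338740597,0.99911458801696962,-0.041981132022255209,-1.25317850290032,-0.059374323779975841,0.041743423498908507,0.99736261022271189,23.949240736358473,0,0,0,1
3,0.99829660317312641,0.0059777928988140345,0.058035834490909585,-1.2526595562078982,-0.0034810692307770258,0.99906786503413503,-0.043026540799207202,-1.1834838019978118,-0.058238941010357495,0.042751222768409716,0.9973868651139326,14.369544441815084,0,0,0,1
4,0.99836121250615728,0.0066749172487486951,0.056836034722327802,-1.2933244203703167,-0.0041702009826868397,0.99901955405428466,-0.044074255988525032,-1.1117169959618387,-0.057074502074037331,0.043765009961159548,0.99741020904946631,4.7898481472716909,0,0,0,1
5,0.9984256082572831,0.0073367607714211677,0.055610041516412204,-1.3306477953500657,-0.0048274977339055215,0.99896976389891279,-0.045123232169024044,-1.0380037378574833,-0.055883808403716456,0.04478373317548956,0.99743241234740476,-4.7898481472716981,0,0,0,1
6,0.99848960873566561,0.0079621971532003299,0.054360874380303521,-1.3645332508534083,-0.0054518475478191764,0.99891860724395221,-0.04617243181941167,-0.96247308869958015,-0.054669722929725086,0.045806326182050987,0.99745325799081463,-14.369544441815087,0,0,0,1
7,0.99855304080359786,0.0085501686153344556,0.053091612506474803,-1.3948932389447819,-0.0060421874360969676,0.99886620002956683,-0.047220826014382655,-0.88525729148595156,-0.053435163262363056,0.046831709931870691,0.99747254311684286,-23.949240736358476,0,0,0,1
8,0.99861574068803149,0.0090996878882787305,0.051805387079243981,-1.4216493202394551,-0.0065975050470318784,0.99881266086436327,-0.048267395042666715,-0.80649153965948595,-0.052183094745796507,0.047858794148895691,0.997490080374419,-33.528937030901872,0,0,0,1
9,0.99867755468361741,0.0096098400209960744,0.05050537343611413,-1.444732366562927,-0.007116840310848957,0.9987581104279819,-0.049311128949934196,-0.726313740404398,-0.050916523399976509,0.048886479000824198,0.9975056991394895,-43.108633325445254,0,0,0,1
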