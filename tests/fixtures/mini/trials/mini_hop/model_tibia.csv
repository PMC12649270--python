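frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.98336115102615274,-0.011346376329955615,0.18130666396108999,-1.9398586920983996,0.10674773821966618,0.84364904705428068,-0.52617602167847832,2.7131105453687026,-0.14698900311760132,0.53677513462210957,0.8308228979836263,-12.789956782584913,0,0,0,1
1,0.98335917764099967,-0.013590287530865101,0.18116299797156554,0.11194632363080609,0.10831189779562089,0.84444758515676088,-0.52457297749581644,2.8449612687935475,-0.1458535585617575,0.53546575988362111,0.8318672727347366,-13.060941433056611,0,0,0,1
2,0.98347186180981727,-0.012633553997715116,0.1806197396236594,2.5609426154952879,0.10707481413086632,0.84501310326157841,-0.52391587062721967,2.724776182633236,-0.14600712724785783,0.53459634176603188,0.83239934536447358,-12.989675883919732,0,0,0,1
3,0.98365144102710078,-0.014470287860281712,0.1795005663906073,5.0266583216434588,0.10766984669755572,0.84624297229098866,-0.52180459557217229,3.0605079166240214,-0.14435043012555621,0.53260064083453185,0.83396613282867416,-13.045644317930657,0,0,0,1
4,0.98376408237148594,-0.013427476966920315,0.17896349655192534,7.2624145362019403,0.10651097869589619,0.84627102463524251,-0.52199690064219639,2.9627552541866877,-0.14444252023912671,0.53258337912961529,0.8339612117010301,-13.063937395257719,0,0,0,1
5,0.98386351844928666,-0.012321146915182222,0.17849584421852766,9.3595099044171057,0.10536451530329047,0.84619346818816943,-0.52235517927037012,2.9090073530420528,-0.14460600257075454,0.53273333266689094,0.83383709457311583,-13.491094833572065,0,0,0,1
6,0.9837910862687812,-0.014521904418131847,0.17872944041249228,11.552487934943441,0.10708932724978459,0.84703614159241003,-0.52063581400575165,2.6622304142370559,-0.1438296720683202,0.53133688854465355,0.83486174682063763,-13.666594857585391,0,0,0,1
7,0.98401397213895336,-0.014197564192387487,0.17752445410794135,13.594475985075448,0.10617812846191768,0.84704998935636788,-0.52079988533764277,2.5290037206169975,-0.14297799715915752,0.53132357815400999,0.83501649542148337,-13.91462656352045,0,0,0,1
8,0.98405062357949169,-0.013012099809082323,0.1774121063833366,15.666585194731773,0.10503690911830048,0.84740377785734577,-0.5204556513248485,2.6035469138231337,-0.14356746830562886,0.53078952752636044,0.83525496676922317,-14.181581481402901,0,0,0,1
9,0.98353059234553208,-0.017973142474959757,0.17984587865731494,17.877641045751499,0.1108765164948772,0.845814769714612,-0.52182734062386948,2.6081685035035806,-0.14273742330029668,0.53317383795737139,0.83387750090010193,-14.166527329155702,0,0,0,1
10,0.98363014753078348,-0.015687989370086402,0.17951495719881741,20.222055081586259,0.10861635165892791,0.84651151219268761,-0.52117247421324309,2.3056213625620341,-0.14378532964413751,0.53213921741849979,0.83435821579484293,-14.535080525079378,0,0,0,1
11,0.9845942058001943,-0.0175358305145237,0.17397340185456664,22.388253139298101,0.10655938420796407,0.84902898655418457,-0.51748901208430886,1.9062838868662995,-0.13863386145492779,0.52805518143366448,0.83781762801886417,-14.703685106336152,0,0,0,1
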