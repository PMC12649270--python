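frame,FE,AA,IE,ML,AP,IS,speed,method,specimen,trial,motion
0,24.812042681740024,1.9360942095691045,1.3423482778241695,-2.0060531946980333,-1.7656664148240253,-39.216461553975833,0.56471542826278487,model,1,mini_hop,hop
1,24.874802523988894,1.8498838098558912,1.330318463694764,-1.8506899724074746,-1.6549935715230539,-39.263084361406911,0.5643642408732461,model,1,mini_hop,hop
2,24.934651630777111,1.7670325061706875,1.3220955362038913,-1.6952203602253118,-1.5544969135859823,-39.311163212304855,0.563284001414878,model,1,mini_hop,hop
3,24.989519464334201,1.6902336247957535,1.3211547140030997,-1.5398391076159559,-1.4724084650028928,-39.362850414979974,0.56152277321093758,model,1,mini_hop,hop
4,25.038412128200068,1.6208896594430546,1.3304099000505134,-1.3841611198183568,-1.4138707583510932,-39.419632266599919,0.55936715061868658,model,1,mini_hop,hop
5,25.081000493051821,1.5589571322734179,1.3519058556007981,-1.226962322068351,-1.3806924684035131,-39.481144406843619,0.55726725473290717,model,1,mini_hop,hop
6,25.117132277557751,1.5033685992759143,1.3863098916295975,-1.0667549142194677,-1.3723864226371933,-39.545099618708129,0.55562769468526085,model,1,mini_hop,hop
7,25.146689665201862,1.4526085287233028,1.4326664531588404,-0.90209765092884986,-1.3875825716979815,-39.608649857629793,0.55467529790245762,model,1,mini_hop,hop
8,25.169652890663997,1.4049731380700512,1.4885938637075191,-0.73180900744161903,-1.4247927215413974,-39.669827257168549,0.55440215284511096,model,1,mini_hop,hop
9,25.186348868480074,1.3587019284492161,1.5507653332858751,-0.55575889585852245,-1.4822135699938705,-39.728036261305817,0.55457122568592709,model,1,mini_hop,hop
10,25.197876820169071,1.312466044451686,1.615897529177645,-0.37531385800980388,-1.5563340032704218,-39.783746947455541,0.55484610600698392,model,1,mini_hop,hop
11,25.206441170106686,1.2658559089763453,1.6818767115171844,-0.1926159135213954,-1.6401870318495249,-39.838103166505022,0.55496805559065721,model,1,mini_hop,hop
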