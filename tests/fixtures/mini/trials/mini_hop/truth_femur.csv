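frame,m00,m01,m02,m03,m10,m11,m12,m13,m20,m21,m22,m23,m30,m31,m32,m33
0,0.99867280068196396,0.04479525452727174,0.025416969722599349,-11.679319475636618,-0.045014620014651598,0.99895328733668309,0.0081248817942820659,2.7992468522809051,-0.025026409310548701,-0.009258233690692284,0.99964391857598456,-1.281829346487217,0,0,0,1
1,0.99867943606303244,0.044960120647424481,0.024859033291593138,-9.5558068437026868,-0.045196801260206323,0.99893717925908376,0.0090421816919775584,2.7423910516975956,-0.024426075015624462,-0.010153789700124611,0.99965007248239457,-1.4171945974750308,0,0,0,1
2,0.99868586367255752,0.045121886058717885,0.024301462900448299,-7.432294211768756,-0.045374943030837854,0.99892033173119366,0.0099642058885818958,2.6713279489727624,-0.023825621619298912,-0.011053789058323455,0.99965501724440309,-1.5487798817019829,0,0,0,1
3,0.99869207739490939,0.045280531672877343,0.023744641502074216,-5.3087815798348261,-0.045548979850091147,0.99890275718076871,0.010889083123681313,2.5864256954577236,-0.023225524391420397,-0.011956385243040754,0.99965875170913387,-1.6762342325460706,0,0,0,1
4,0.99869807206280647,0.045436036547451784,0.023188950836378647,-3.1852689479008944,-0.045718850132179696,0.99888447481180598,0.011814936416831564,2.4881241379669734,-0.022626259094791899,-0.012859726389045204,0.99966128255353282,-1.7992177014846449,0,0,0,1
5,0.99870384345721941,0.045588377854169901,0.022634771224892988,-1.0617563159669636,-0.045884496238691133,0.99886551061022144,0.012739886903071167,2.3769325400963752,-0.022028301539141686,-0.013761959090439703,0.99966262429546382,-1.9174022648111857,0,0,0,1
6,0.99870938830438161,0.045737530861457369,0.022082481368390836,1.0617563159669654,-0.046045864518597816,0.99884589729392381,0.013662057671932354,2.253426943918984,-0.021432127132485681,-0.014661232205838129,0.99966279924621759,-2.0304726985459967,0,0,0,1
7,0.99871470426993081,0.045883468931098806,0.021532458147496315,3.1852689479008962,-0.046202905331538591,0.99882567420740487,0.014579577601844508,2.1182471857265552,-0.020838210430592956,-0.015555700658350734,0.99966183740456871,-2.1381274192072359,0,0,0,1
8,0.99871978995020894,0.04602616352895661,0.020985076426270559,5.3087815798348288,-0.046355573054428861,0.99880488716141136,0.015490585181840513,1.972093581277073,-0.020247024685276137,-0.016443529222344332,0.99965977629296854,-2.24007928819977,0,0,0,1
9,0.99872464486075729,0.046165584249588131,0.020440708858754968,7.432294211768756,-0.046503826071545941,0.99878358821871693,0.016393232312514144,1.8157232977207873,-0.019659041392234958,-0.017322896288982228,0.99965666073692505,-2.3360563776763681,0,0,0,1
10,0.99872926942205464,0.046301698854532676,0.019899725698440649,9.5558068437026904,-0.046647626748325531,0.99876183542745101,0.01728568807823502,1.6499464310004577,-0.019074729839185577,-0.0181919976026081,0.9996525425890681,-2.4258026958285126,0,0,0,1
11,0.99873366494255045,0.04643447332397254,0.019362494610623081,11.679319475636618,-0.046786941389193086,0.99873969250387862,0.018166142482707179,1.4756218090473212,-0.018494556655008952,-0.019049049960118494,0.99964748039984141,-2.5090788696723352,0,0,0,1
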