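n,c_mse,c_bias,c_inv,q025,q975,mc_samples,seed
3,7.631981371213408e-06,0.07143493658994848,0.75,0.4236957142900836,39.630207658238916,1000000,20260924.0
4,0.08083333221819482,0.4550081389405394,0.7777777777777779,0.5258960100199673,8.240210159754437,1000000,20260925.0
5,0.35103194019893497,0.5913949078683165,0.7986111111111113,0.5832655344653441,4.866999225265294,1000000,20260926.0
6,0.4918441623492749,0.6610809272830509,0.815,0.6218349163474307,3.6941716822277306,1000000,20260927.0
7,0.5747290874342499,0.705097357440992,0.8283333333333335,0.6488647743233626,3.1127187230423736,1000000,20260928.0
8,0.6294388392141453,0.7366058772136427,0.8394557823129253,0.6704043264370422,2.7659493989555473,1000000,20260929.0
9,0.6688543324322492,0.7603765604058815,0.8489158163265307,0.687397946192016,2.5237385180610836,1000000,20260930.0
10,0.6985785711186564,0.77853024786525,0.8570877425044092,0.7031327877315805,2.354646697465337,1000000,20260931.0
11,0.7245202379483425,0.795046129802815,0.8642372134038802,0.7158968513106495,2.221983620139141,1000000,20260932.0
12,0.7438992288464497,0.807835821718669,0.8705588351042898,0.7254214856945957,2.1209985098834796,1000000,20260933.0
13,0.7611781966058221,0.8191369225976308,0.8761989483580394,0.735052944780195,2.0379937958829646,1000000,20260934.0
14,0.7751864399014547,0.8283890086629289,0.8812700476162015,0.7436692231406498,1.966089905853586,1000000,20260935.0
15,0.7877499911288498,0.8370574791907709,0.8858602478107971,0.7503536777463451,1.9055154524290996,1000000,20260936.0
16,0.7986438915030759,0.8444768504090349,0.8900396957539815,0.7576060496696485,1.854474236812147,1000000,20260937.0
17,0.8086569661468581,0.8514372616027124,0.8938650296462796,0.7625940586463843,1.813113458046808,1000000,20260938.0
18,0.8175118938824615,0.8577884318068124,0.8973825536487733,0.7686038811548231,1.7742938513484479,1000000,20260939.0
19,0.8250944806866949,0.8630256861374597,0.9006305441642812,0.7726356965584349,1.740852708551386,1000000,20260940.0
20,0.8321400794024577,0.8680754257499887,0.9036409557225917,0.7781507044262548,1.7117003188061373,1000000,20260941.0
21,0.8384050722686898,0.8725643872936542,0.9064407031578493,0.7818778269286779,1.6806265092138537,1000000,20260942.0
22,0.8447147656944822,0.8771896396935136,0.9090526392743333,0.7862567038720534,1.656001844226857,1000000,20260943.0
23,0.8499412673043987,0.880895523429706,0.9114963100541185,0.7901662053312831,1.6342140017277111,1000000,20260944.0
24,0.8546304981999173,0.8841634679745348,0.9137885449286873,0.7935553952183841,1.6135166404557642,1000000,20260945.0
25,0.85931559967807,0.887674674376812,0.9159439231089896,0.7968425365793317,1.593169988837636,1000000,20260946.0
26,0.8638075098394323,0.8909951056311395,0.9179751456306814,0.8001795964452209,1.5770860650229823,1000000,20260947.0
27,0.8678113815862468,0.8939290835390483,0.9198933348649135,0.8036845105253426,1.5619371689156225,1000000,20260948.0
28,0.8714514738999267,0.8966008473789774,0.921708277648065,0.8056035092123107,1.5454443679766239,1000000,20260949.0
29,0.8748060726938359,0.8990890524896867,0.9234286241666342,0.8088745842645143,1.531408831667497,1000000,20260950.0
30,0.8781592604090869,0.9016397335296917,0.925062051813286,0.810972104643233,1.5186400000158642,1000000,20260951.0
40,0.9028408535539891,0.9203062636307079,0.9378260988141328,0.8310815729080067,1.421050451078044,1000000,20260961.0
50,0.9185089443111858,0.932433226441988,0.9464454647463983,0.8450145003487858,1.3613972260679192,1000000,20260971.0
75,0.9411177133235027,0.9503837600658379,0.9595331965398967,0.868151787599691,1.276620707320569,1000000,20260996.0
100,0.9530793332852558,0.9600458839982821,0.9670441402016118,0.8816323917868565,1.230684010686884,1000000,20261021.0
150,0.9662507433849962,0.9709080399794559,0.975527068370371,0.8997244186360739,1.1794580992043855,1000000,20261071.0
200,0.97333438466862,0.9768321511334112,0.9802901835027591,0.9106531661135281,1.1511682622165436,1000000,20261121.0
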