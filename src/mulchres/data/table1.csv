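image_id,mulch,block,t_ot,t_rc,t_mt,t_le,a_ot,a_rc,a_mt,a_le,a_r
1,1,1,0.2902,0.2874,0.2468,0.5059,50.9052,49.4967,52.9680,39.8214,49.0100
2,1,2,0.2745,0.2717,0.2297,0.4667,46.5797,45.5628,50.4214,38.7190,55.7600
3,1,3,0.3451,0.3425,0.2158,0.5529,70.6396,70.8865,82.7414,61.2655,86.7600
4,1,4,0.2706,0.2677,0.2494,0.5098,46.4310,45.7977,47.7424,27.5502,39.7300
5,1,5,0.2353,0.2283,0.2390,0.4667,45.2831,46.4100,44.8275,9.6671,29.0600
6,1,6,0.2824,0.2795,0.2430,0.1804,43.7783,43.8106,45.0526,67.6796,45.0500
7,2,1,0.3255,0.3228,0.2691,0.5843,64.9501,63.4503,68.4051,43.6728,59.9000
8,2,2,0.2784,0.2756,0.2483,0.1922,46.8627,44.7348,47.8013,65.0698,45.5200
9,2,3,0.2745,0.2677,0.2499,0.1412,36.4270,35.7161,38.2370,57.5681,33.7800
10,2,4,0.3216,0.3189,0.2599,0.5608,68.6014,68.0766,71.7309,52.9240,71.0700
11,2,5,0.3137,0.3189,0.2897,0.3490,49.5972,50.1565,51.2083,52.3749,52.0200
12,2,6,0.3255,0.3228,0.2819,0.5529,61.5203,62.4738,66.2118,38.5616,54.2500
13,3,1,0.2588,0.2559,0.2616,0.0902,24.5614,24.6451,24.4695,45.8991,22.2100
14,3,2,0.2745,0.2677,0.2406,0.1804,31.0725,31.3840,32.8444,44.1760,23.8300
15,3,3,0.2667,0.2598,0.2400,0.1176,19.3475,18.8066,19.6754,45.0813,23.3600
16,3,4,0.2392,0.2362,0.2332,0.1412,28.6458,28.8813,29.0930,46.7529,29.2300
17,3,5,0.1569,0.1378,0.3919,0.9961,1.6047,1.9750,0.6406,0.0000,2.7600
18,3,6,0.2118,0.2047,0.4327,0.1529,12.4904,7.4138,0.8420,44.7230,4.5300
19,4,1,0.2353,0.2323,0.2297,0.4706,47.0578,47.1434,47.3097,6.9027,26.3000
20,4,2,0.3098,0.3071,0.2517,0.1333,42.9258,43.0054,45.3668,60.3160,42.6000
21,4,3,0.2980,0.2953,0.2773,0.1569,47.2435,46.5150,47.6497,66.6117,48.9300
22,4,4,0.2980,0.2953,0.2662,0.1608,46.5599,46.6459,47.7724,63.7267,47.6600
23,4,5,0.3059,0.2992,0.2622,0.2275,45.0941,45.9767,49.0865,59.3983,42.4800
24,4,6,0.2902,0.2874,0.2439,0.1490,40.0192,35.5562,41.6854,59.2816,40.7600
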