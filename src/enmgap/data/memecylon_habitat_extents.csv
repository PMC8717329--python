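species,endemic,category,occurrences,current_km2,kappa,breadth,area_B26_2050,pct_B26_2050,area_B45_2050,pct_B45_2050,area_B85_2050,pct_B85_2050,area_M26_2050,pct_M26_2050,area_M45_2050,pct_M45_2050,area_M85_2050,pct_M85_2050,area_B26_2070,pct_B26_2070,area_B45_2070,pct_B45_2070,area_B85_2070,pct_B85_2070,area_M26_2070,pct_M26_2070,area_M45_2070,pct_M45_2070,area_M85_2070,pct_M85_2070
M. capitellatum,False,nonendemic_dry,25,20169,0.42,0.81,33562,64,28055,39,34954,73,2447,21,25455,26,25206,24,27147,34,24254,20,26568,31,33561,66,29072,44,26519,31
M. clarkeanum,False,nonendemic_wet,47,5656,0.56,0.23,22846,30,7505,32,0,-100,16923,199,15392,172,8805,55,20990,271,15280,170,7013,23,21566,281,18252,222,8799,55
M. cuneatum,True,narrow_endemic_montane,15,4812,0.11,0.11,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100
M. discolor,True,narrow_endemic_lowland,18,6094,0.49,0.11,10393,70,19087,213,19087,213,24509,302,11845,94,8510,39,20172,231,19966,227,9572,57,15093,147,12986,113,11565,89
M. fuscescens,True,narrow_endemic_lowland,17,5852,0.29,0.49,3355,-43,5862,0,5657,-3,161,-97,3881,-33,2952,-49,1427,-76,5146,-12,2360,-60,21,-99,2208,-62,218,-96
M. grande,False,nonendemic_wet,25,4453,0.42,0.53,10023,125,8946,101,12233,175,6001,35,4655,5,2768,-38,8695,95,7841,76,9606,116,4169,-6,8790,97,4089,-8
M. hookeri,False,nonendemic_wet,18,8498,0.33,0.46,26881,216,28719,238,25305,198,24783,192,27314,221,25992,206,24321,186,50007,488,29110,243,51511,506,28136,231,24654,190
M. orbiculare,True,narrow_endemic_lowland,20,6451,0.11,0.33,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100
M. ovoideum,True,narrow_endemic_montane,17,3063,0.37,0.28,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100
M. parvifolium,True,narrow_endemic_montane,16,4027,0.38,0.21,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100
M. petiolatum,False,nonendemic_dry,21,18259,0.47,0.82,23143,27,22070,21,21768,19,22594,24,23702,30,21813,19,18582,2,21208,16,18645,2,20258,11,22870,25,26277,44
M. procerum,True,narrow_endemic_lowland,18,3146,0.78,0.43,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100
M. rhinophyllum,True,wide_endemic,21,14152,0.11,0.50,26881,90,28719,103,25305,79,24783,75,27314,93,25992,84,24321,72,12861,-9,29110,106,24654,74,28136,99,25561,81
M. rivulare,True,narrow_endemic_lowland,35,5306,0.85,0.43,5320,0.2,11032,107,0,-100,5382,1,15208,186,12510,135,9091,71,11851,123,11363,114,6003,13,19537,268,11881,123
M. rostratum,True,narrow_endemic_lowland,25,7753,0.60,0.53,2854,-63,11851,52,4511,-41,4020,-48,15208,96,12510,61,3598,-53,3598,-53,5312,-31,6379,-17,6379,-17,5170,-33
M. rotundatum,True,narrow_endemic_montane,15,4260,0.59,0.37,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100
M. royenii,True,wide_endemic,20,15993,0.40,0.62,35229,120,37671,136,34318,115,43038,169,36760,130,42842,168,33737,111,42296,164,38346,140,34709,117,36644,129,43509,172
M. sylvaticum,True,wide_endemic,32,17843,0.48,0.71,34416,93,23225,30,32147,80,24119,35,24603,38,30808,73,15454,-13,32032,80,26742,50,27008,51,29088,63,16963,-5
M. umbellatum,False,nonendemic_dry,30,19077,0.48,0.81,18068,-5,19841,4,16321,-14,20420,7,17985,-6,16767,-12,19749,4,17320,-9,18850,-1,19743,3,19142,0,16637,-13
M. urceolatum,True,wide_endemic,20,9640,0.64,0.53,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100,0,-100
M. varians,True,narrow_endemic_lowland,31,7314,0.36,0.49,7853,7,14282,95,15808,116,25599,250,15993,118,9294,27,16189,121,18431,150,15296,109,47703,552,22625,209,18039,146
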