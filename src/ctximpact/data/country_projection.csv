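country,n_facilities,total_ctx_donated,chronic_ctx_donated,acute_ctx_donated,unique_patients,unique_ci_low,unique_ci_high,total_beneficiaries,total_ci_low,total_ci_high,chronic_beneficiaries,chronic_ci_low,chronic_ci_high,acute_beneficiaries,acute_ci_low,acute_ci_high
El Salvador,338,1857380,1774100,83280,173347,128257,215826,665562,530377,813479,5525,3994,7062,660036,524850,807623
Ghana,19,56049,42190,13859,12341,9256,16219,20632,16982,24880,3382,2467,4513,17250,13566,21523
India,16,37739,25844,11896,11549,8474,15450,30022,24494,36561,11690,8064,17031,18332,14507,22510
Nicaragua,102,657553,534132,123422,59715,45716,75790,169533,135564,201124,8017,6076,10106,161516,127944,194107
Peru,27,208164,110867,97297,45378,32918,60538,81688,68007,99033,34493,23927,47454,47195,37027,57441
Philippines,701,902378,702467,199912,105992,78167,138259,402486,324763,479158,23880,17884,31018,378605,299627,456098
Romania,11,37371,18697,18674,2136,1549,2844,3904,3168,4961,1469,1043,2052,2436,1801,3299
Tanzania,4,93573,73788,19786,12109,8333,17503,27995,21848,35185,1895,1227,2848,26100,20090,33372
U.S.,984,2598043,1138266,1459777,177237,134199,223571,442696,347189,571629,82662,62531,103943,360034,266306,486345
West Bank,23,289849,250416,39433,100574,71537,139987,102140,81397,126709,8652,6228,11738,93489,72803,119613
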