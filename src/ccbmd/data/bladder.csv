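study_id,location,water_intake,group_label,dose_low,dose_high,midpoint,or,or_low,or_high,cases_raw,noncases_raw,cases_eff,noncases_eff,n_raw,n_eff
Ferreccio2000,Chile,1.80,0-59,0,59,26.55,1,,,23,138,19,142,161,161
Ferreccio2000,Chile,1.80,60-199,60,199,116.55,0.84,0.46,1.52,27,193,22,198,220,220
Ferreccio2000,Chile,1.80,200-799,200,799,449.55,2.50,1.48,4.22,60,144,51,153,204,204
Ferreccio2000,Chile,1.80,>=800,800,,1080,4.44,2.75,7.15,122,165,107,180,287,287
Kurttio1999,Finland,1.60,<0.1,,0.1,0.04,1,,,26,112,13,125,138,138
Kurttio1999,Finland,1.60,0.1-0.5,0.1,0.5,0.24,0.81,0.41,1.63,18,51,5,64,69,69
Kurttio1999,Finland,1.60,>0.5,0.5,,0.6,1.51,0.67,3.38,17,51,9,59,68,68
Pu2007,Taiwan,2.23,<=27.8,,27.8,31.0,1,,,24,104,18,110,128,128
Pu2007,Taiwan,2.23,27.8-61.0,27.8,61.0,49.51,1.90,1.10,3.40,44,104,35,113,148,148
Pu2007,Taiwan,2.23,>61.0,61.0,,102.02,5.30,3.10,9.00,109,105,99,115,214,214
Steinmaus2013,Chile,1.80,<26,,26,11.7,1,,,33,202,14,221,235,235
Steinmaus2013,Chile,1.80,26-79,26,79,47.25,0.92,0.52,1.61,33,189,12,210,222,222
Steinmaus2013,Chile,1.80,80-197,80,197,124.65,2.62,1.53,4.50,71,142,30,183,213,213
Steinmaus2013,Chile,1.80,>197,197,,265.95,6.00,3.38,10.64,95,107,56,146,202,202
Wu2013,Taiwan,2.23,<15.5,,15.5,8.64,1,,,44,196,27,213,240,240
Wu2013,Taiwan,2.23,15.5-42.5,15.5,42.5,32.34,1.42,0.90,2.25,63,196,40,219,259,259
Wu2013,Taiwan,2.23,>42.5,42.5,,71.08,4.13,2.69,6.35,192,202,135,259,394,394
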