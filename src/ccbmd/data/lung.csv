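study_id,location,water_intake,group_label,dose_low,dose_high,midpoint,or,or_low,or_high,cases_raw,noncases_raw,cases_eff,noncases_eff,n_raw,n_eff
Ferreccio1998,Chile,1.80,0-10,0,10,4.5,1,,,6,70,5,71,76,76
Ferreccio1998,Chile,1.80,10-29,10,29,17.55,1.70,0.50,5.10,9,68,8,69,77,77
Ferreccio1998,Chile,1.80,30-49,30,49,35.55,3.90,1.20,13.40,7,24,7,24,31,31
Ferreccio1998,Chile,1.80,50-199,50,199,112.05,5.50,2.20,13.50,52,130,51,131,182,182
Ferreccio1998,Chile,1.80,200-400,200,400,270,9.00,3.60,22.00,77,127,79,125,204,204
Ferreccio2000,Chile,1.80,0-59,0,59,26.55,1,,,48,138,32,154,186,186
Ferreccio2000,Chile,1.80,60-199,60,199,116.55,0.77,0.49,1.21,52,193,34,211,245,245
Ferreccio2000,Chile,1.80,200-799,200,799,449.55,1.38,0.89,2.13,69,144,48,165,213,213
Ferreccio2000,Chile,1.80,>=800,800,,1080,2.39,1.61,3.54,137,165,100,202,302,302
Mostafa2008,Bangladesh,3.50,0-10,0,10,8.75,1,,,354,186,109,431,540,540
Mostafa2008,Bangladesh,3.50,11-50,11,50,52.5,1.13,0.91,1.40,1303,576,128,448,1879,576
Mostafa2008,Bangladesh,3.50,51-100,51,100,131.25,1.28,0.92,1.77,208,84,71,221,292,292
Smith2009,USA,1.80,0-9,0,9,4.05,1,,,11,92,8,95,103,103
Smith2009,USA,1.80,10-59,10,59,31.05,0.70,0.30,1.70,7,81,5,83,88,88
Smith2009,USA,1.80,60-199,60,199,116.55,3.40,1.80,6.50,35,87,27,95,122,122
Smith2009,USA,1.80,200-399,200,399,269.55,4.70,2.00,11.00,23,44,19,48,67,67
Smith2009,USA,1.80,400-699,400,699,494.55,5.70,1.90,16.90,11,12,7,16,23,23
Smith2009,USA,1.80,700-999,700,999,764.55,7.10,3.40,14.80,64,103,62,105,167,167
Steinmaus2013,Chile,1.80,<26,,26,11.7,1,,,61,202,21,242,263,263
Steinmaus2013,Chile,1.80,26-79,26,79,47.25,0.98,0.62,1.53,61,189,20,230,250,250
Steinmaus2013,Chile,1.80,80-197,80,197,124.65,1.70,1.05,2.75,85,142,29,198,227,227
Steinmaus2013,Chile,1.80,>197,197,,265.95,3.18,1.90,5.30,99,107,45,161,206,206
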