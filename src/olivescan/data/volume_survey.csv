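variety,speed_kmh,beating_freq_hz,sensor,phase,convex_hull_m3,alphashape_m3,delta_volume_m3,alpha_value,point_count,delta_point_count
Manzanilla Cacerena,3,470,1,BH,51.32,38.63,,3.20,941169,
Manzanilla Cacerena,3,470,1,AH,49.94,37.60,1.02,3.15,821556,119613
Manzanilla Cacerena,3,470,2,BH,49.24,40.93,,3.30,1073330,
Manzanilla Cacerena,3,470,2,AH,45.78,39.05,1.87,3.30,812332,260998
Manzanilla Cacerena,2,470,1,BH,66.58,58.01,,3.00,1307456,
Manzanilla Cacerena,2,470,1,AH,62.68,56.96,1.05,3.10,1156895,150561
Manzanilla Cacerena,2,470,2,BH,61.17,56.83,,3.10,984536,
Manzanilla Cacerena,2,470,2,AH,57.22,55.42,1.41,3.05,843732,140804
Manzanilla de Sevilla,3,470,1,BH,57.52,48.43,,3.20,969025,
Manzanilla de Sevilla,3,470,1,AH,56.01,46.78,1.64,3.10,738178,230847
Manzanilla de Sevilla,3,470,2,BH,55.79,48.19,,3.00,1048921,
Manzanilla de Sevilla,3,470,2,AH,55.78,47.08,1.10,3.00,875640,173281
Manzanilla de Sevilla,2,470,1,BH,67.16,47.98,,3.50,1090924,
Manzanilla de Sevilla,2,470,1,AH,67.05,47.39,0.59,3.50,984563,106361
Manzanilla de Sevilla,2,470,2,BH,67.61,45.09,,3.50,1142788,
Manzanilla de Sevilla,2,470,2,AH,69.42,44.87,0.21,3.50,1089874,52914
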