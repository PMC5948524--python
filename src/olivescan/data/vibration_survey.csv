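variety,speed_kmh,beating_freq_hz,tree,max_acc_g,duration_s
Manzanilla Cacerena,3,470,1,7.07,3.25
Manzanilla Cacerena,3,470,2,6.62,3.13
Manzanilla Cacerena,2,470,1,7.35,4.38
Manzanilla Cacerena,2,470,2,7.07,5.25
Manzanilla Cacerena,2,430,1,5.46,4.12
Manzanilla Cacerena,2,430,2,4.71,4.00
Manzanilla de Sevilla,3,470,1,7.04,4.50
Manzanilla de Sevilla,3,470,2,5.14,3.50
Manzanilla de Sevilla,2,470,1,7.40,4.68
Manzanilla de Sevilla,2,470,2,8.24,5.37
Manzanilla de Sevilla,2,430,1,4.25,4.31
Manzanilla de Sevilla,2,430,2,4.83,4.75
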