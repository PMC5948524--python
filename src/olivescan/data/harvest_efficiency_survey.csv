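variety,speed_kmh,beating_freq_hz,time_to_harvest_h_per_ha,fruit_removal_pct,fruit_on_ground_pct
Manzanilla Cacerena,3,470,1.1,99.5,2.1
Manzanilla Cacerena,2,470,1.6,99.7,1.4
Manzanilla Cacerena,2,430,1.8,96.8,2.3
Manzanilla de Sevilla,3,470,1.1,99.9,1.9
Manzanilla de Sevilla,2,470,1.7,99.5,2.0
Manzanilla de Sevilla,2,430,1.5,98.8,3.3
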