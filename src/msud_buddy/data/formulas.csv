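name,category,leucine_mg_per_100g,isoleucine_mg_per_100g,valine_mg_per_100g,protein_g_per_100g,energy_kcal_per_100g
Nan 1,commercial,106.4,51.6,53.6,12.3,506
Similac,commercial,1079,573,641,10.83,526
Aptamil,commercial,1020,480,520,4.7,485
Ketonex-1,medical,0,0,0,15,480
Anamix,medical,0,0,0,13.1,466
Comida,medical,0,0,0,12,205
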