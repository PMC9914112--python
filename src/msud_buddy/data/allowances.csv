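age_band,isoleucine_mg_per_kg,leucine_mg_per_kg,valine_mg_per_kg,protein_g_per_kg,energy_kcal_per_kg,fluid_ml_per_kg
1,40,66.5,46.5,3.45,120,100
2,48,79.5,55.5,3.34,120,100
3,56,92.5,64.5,3.16,120,100
4,48.5,56,56,3,120,100
5,40.5,68,47,2.84,120,100
6,47.5,80,55,2.68,120,100
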