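category,period,richness_km2,protected_all_km2,conservation_forest_km2,forest_km2
wide_endemic,current,7235,425,108,1288
narrow_endemic_lowland,current,291,35,13,125
narrow_endemic_montane,current,1326,352,180,615
nonendemic_dry,current,3946,106,93,786
nonendemic_wet,current,4239,250,47,840
wide_endemic,2050-M26,6875,7,7,
narrow_endemic_lowland,2050-M26,356,0.7,0.06,
narrow_endemic_montane,2050-M26,,,,
nonendemic_dry,2050-M26,1070,10,8,
nonendemic_wet,2050-M26,19,0,0,
wide_endemic,2070-M26,9463,22,22,
narrow_endemic_lowland,2070-M26,99,0.2,0.09,
narrow_endemic_montane,2070-M26,,,,
nonendemic_dry,2070-M26,46,0.9,0.9,
nonendemic_wet,2070-M26,2059,16,6,
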