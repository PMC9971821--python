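id,BW_kg,dose_mg_per_kg,FracMetab_to_cx,FracMetab_to_OH
A,83,0.717,0.02,0.396
B,75,0.639,0.017,0.340
C,76,0.781,0.02,0.374
D,74,0.783,0.023,0.359
E,90,0.775,0.018,0.334
F,108,0.733,0.018,0.329
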